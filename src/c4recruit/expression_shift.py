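"""Expression-shift statistics: normalization, qPCR quantification,
stepwise light-response testing, and paralog dominance switches.

The recruitment signature looked for here is a *dominance switch*: the
paralog that is the minor transcript in C3 leaves (but dominant in roots)
becomes the dominant leaf/mesophyll transcript in C4 species. Light
responsiveness is scored per consecutive time-point interval with Welch's
two-sample t-test on relative abundances; significance stars follow the
conventional bins (*: 0.05–0.01, **: 0.01–0.001, ***: < 0.001) with a
separately reported marginal band (0.05–0.10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("leaf", "root", "shoot")
CELLS = ("MC", "BSC", "whole")


# ---------------------------------------------------------------------------
# containers

@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with complete sample metadata."""

    values: pd.DataFrame  # genes x samples
    meta: pd.DataFrame  # indexed by sample: species, ptype, tissue, cell, replicate
    unit: str = "TPM"

    def __post_init__(self):
        if self.unit not in ("TPM", "FPKM", "relative"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("negative abundances")
        need = {"species", "ptype", "tissue", "cell", "replicate"}
        missing_cols = need - set(self.meta.columns)
        if missing_cols:
            raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
        unmet = set(self.values.columns) - set(self.meta.index)
        if unmet:
            raise ValueError(f"samples without metadata: {sorted(unmet)}")

    def select(self, **filters) -> pd.DataFrame:
        """Columns whose metadata match all filters (value or collection)."""
        mask = pd.Series(True, index=self.meta.index)
        for key, val in filters.items():
            col = self.meta[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(val)
            else:
                mask &= col == val
        samples = [s for s in self.values.columns if mask.get(s, False)]
        return self.values[samples]


@dataclass
class LightSeries:
    """Replicate abundance time course for one gene under illumination."""

    gene: str
    times: tuple[float, ...]
    replicates: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("time points must be strictly increasing")
        for t in self.times:
            arr = np.asarray(self.replicates[t], dtype=float)
            if arr.size < 2:
                raise ValueError(f"time {t}: need >= 2 replicates")
            self.replicates[t] = arr


@dataclass(frozen=True)
class QpcrRecord:
    gene: str
    sample: str
    ct_target: float
    ct_reference: float  # reference-gene (ACTIN7 role) Ct in the same sample

    def __post_init__(self):
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


# ---------------------------------------------------------------------------
# normalization

def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; every column sums to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some genes")
    rate = counts.div(lengths / 1e3, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def counts_to_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                   library_size: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some genes")
    lib = counts.sum(axis=0) if library_size is None else library_size
    per_million = counts.div(lib / 1e6, axis=1)
    return per_million.div(lengths / 1e3, axis=0)


# ---------------------------------------------------------------------------
# qPCR

def relative_abundance(q: QpcrRecord) -> float:
    """2^-(Ct_target - Ct_reference): one cycle earlier = twice as abundant."""
    return 2.0 ** (-(q.ct_target - q.ct_reference))


def qpcr_table(records: list[QpcrRecord]) -> pd.DataFrame:
    rows = [(q.gene, q.sample, q.ct_target, q.ct_reference,
             relative_abundance(q)) for q in records]
    return pd.DataFrame(rows, columns=["gene", "sample", "ct_target",
                                       "ct_reference", "relative_abundance"])


# ---------------------------------------------------------------------------
# stepwise light-response test

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch t statistic, Welch–Satterthwaite df, two-sided p.

    Zero variance on both sides: p = 1 for equal means (no evidence of
    change), p = 0 for different means (documented convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        equal = math.isclose(x.mean(), y.mean(), rel_tol=0, abs_tol=0)
        return (0.0 if equal else math.inf,
                float(len(x) + len(y) - 2),
                1.0 if equal else 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2 ** 2 / ((vx / len(x)) ** 2 / (len(x) - 1)
                     + (vy / len(y)) ** 2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def star_bin(p: float) -> tuple[str, bool]:
    """(stars, marginal): *: 0.05-0.01, **: 0.01-0.001, ***: < 0.001."""
    if p < 0.001:
        return "***", False
    if p < 0.01:
        return "**", False
    if p < 0.05:
        return "*", False
    return "", 0.05 <= p < 0.10


def stepwise_light_test(series: LightSeries,
                        log_scale: bool = False) -> pd.DataFrame:
    """Welch t-test of each time point against the preceding one.

    Returns one row per interval with direction (up/down), the p-value,
    its star bin, and the marginal flag; ``first_significant_time`` is
    attached as DataFrame attrs. No multiplicity correction is applied
    across intervals.
    """
    rows = []
    first_sig = None
    for t0, t1 in zip(series.times, series.times[1:]):
        x = series.replicates[t0]
        y = series.replicates[t1]
        if log_scale:
            x, y = np.log2(x), np.log2(y)
        t, df, p = welch_t(x, y)
        stars, marginal = star_bin(p)
        direction = "up" if y.mean() > x.mean() else (
            "down" if y.mean() < x.mean() else "flat")
        if stars and first_sig is None:
            first_sig = t1
        rows.append((series.gene, t0, t1, direction, t, df, p, stars, marginal))
    out = pd.DataFrame(rows, columns=["gene", "t_from", "t_to", "direction",
                                      "t_stat", "df", "p", "stars", "marginal"])
    out.attrs["first_significant_time"] = first_sig
    return out


# ---------------------------------------------------------------------------
# dominance and recruitment switch

def dominance_index(m: ExpressionMatrix, gene_a: str, gene_b: str,
                    **stratum) -> float:
    """log2(mean_a / mean_b) over the samples matching the stratum filters."""
    sub = m.select(**stratum)
    if sub.shape[1] == 0:
        raise ValueError(f"no samples match stratum {stratum}")
    mean_a = sub.loc[gene_a].mean()
    mean_b = sub.loc[gene_b].mean()
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("dominance index needs positive stratum means")
    return float(np.log2(mean_a / mean_b))


def _dominant(m, gene_a, gene_b, **stratum) -> str | None:
    try:
        idx = dominance_index(m, gene_a, gene_b, **stratum)
    except ValueError:
        return None
    return gene_a if idx > 0 else gene_b


def recruitment_switch(m: ExpressionMatrix, gene_a: str, gene_b: str,
                       c3_types: tuple[str, ...] = ("C3",),
                       c4_types: tuple[str, ...] = ("C4",)) -> dict:
    """Dominance calls per stratum and the C3-vs-C4 switch flags.

    A recruitment switch is flagged for the paralog that is dominant in
    C4 leaf (and, when cell-resolved data exist, in C4 mesophyll) while
    the *other* paralog dominates the same stratum in C3 species.
    """
    calls = {
        "C3": {
            "leaf": _dominant(m, gene_a, gene_b, ptype=c3_types, tissue="leaf"),
            "root": _dominant(m, gene_a, gene_b, ptype=c3_types, tissue="root"),
            "MC": _dominant(m, gene_a, gene_b, ptype=c3_types, cell=("MC", "whole")),
            "BSC": _dominant(m, gene_a, gene_b, ptype=c3_types, cell="BSC"),
        },
        "C4": {
            "leaf": _dominant(m, gene_a, gene_b, ptype=c4_types, tissue="leaf"),
            "root": _dominant(m, gene_a, gene_b, ptype=c4_types, tissue="root"),
            "MC": _dominant(m, gene_a, gene_b, ptype=c4_types, cell="MC"),
            "BSC": _dominant(m, gene_a, gene_b, ptype=c4_types, cell="BSC"),
        },
    }
    leaf_switch = (calls["C3"]["leaf"] is not None
                   and calls["C4"]["leaf"] is not None
                   and calls["C3"]["leaf"] != calls["C4"]["leaf"])
    mc_switch = (calls["C3"]["MC"] is not None
                 and calls["C4"]["MC"] is not None
                 and calls["C3"]["MC"] != calls["C4"]["MC"])
    have_cells = calls["C3"]["MC"] is not None and calls["C4"]["MC"] is not None
    switch = leaf_switch and (mc_switch if have_cells else True)
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "calls": calls,
        "leaf_switch": leaf_switch,
        "mc_switch": mc_switch,
        "switch": switch,
        "recruited_gene": calls["C4"]["leaf"] if switch else None,
    }


# ---------------------------------------------------------------------------
# TSV I/O

def load_expression(values_path, meta_path, unit: str = "TPM") -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, meta=meta, unit=unit)


def load_qpcr(path) -> list[QpcrRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "sample", "ct_target", "ct_reference"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: qPCR TSV needs columns {sorted(need)}")
    return [QpcrRecord(r.gene, r.sample, float(r.ct_target),
                       float(r.ct_reference))
            for r in df.itertuples(index=False)]
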