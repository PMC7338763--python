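"""Branch-site test of episodic positive selection on codon alignments.

Implements the classical branch-site mixture (four site classes) over a
Goldman–Yang-style codon substitution process restricted to single
nucleotide changes, with codon equilibrium frequencies fixed uniform at
1/61. Foreground branches may host a site class with omega2 >= 1; the
null pins omega2 = 1 and the two models are compared by a chi-square(1)
likelihood-ratio test, with Benjamini–Hochberg adjustment across genes.

Site classes and their (background, foreground) omegas:

    class 0   (omega0, omega0)   proportion p0
    class 1   (1, 1)             proportion p1
    class 2a  (omega0, omega2)   proportion (1-p0-p1) * p0/(p0+p1)
    class 2b  (1, omega2)        proportion (1-p0-p1) * p1/(p0+p1)

With uniform frequencies the rate matrix is symmetric, so transition
probabilities come from one symmetric eigendecomposition per distinct
omega instead of a matrix exponential per branch.

Branch lengths are taken from the input tree up to a single global rate
scale, which is estimated under the null and reused in the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from Bio.Data.CodonTable import standard_dna_table

from .seq_core import GAP, PhyloTree, read_newick_string

# ---------------------------------------------------------------------------
# codon machinery

_STOPS = set(standard_dna_table.stop_codons)
CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in _STOPS
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO = tuple(standard_dna_table.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _classify_pairs():
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = AMINO[i] != AMINO[j]
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _classify_pairs()

# change counts by category, for closed-form mean rates
_N_SYN_TV = int((_SINGLE & ~_TRANSITION & ~_NONSYN).sum())
_N_SYN_TS = int((_SINGLE & _TRANSITION & ~_NONSYN).sum())
_N_NS_TV = int((_SINGLE & ~_TRANSITION & _NONSYN).sum())
_N_NS_TS = int((_SINGLE & _TRANSITION & _NONSYN).sum())


def mean_substitution_rate(kappa: float, omega: float) -> float:
    """Mean rate of the *unscaled* generator under uniform frequencies."""
    return (_N_SYN_TV + kappa * _N_SYN_TS + omega * _N_NS_TV
            + kappa * omega * _N_NS_TS) / N_CODONS


def mixture_rate_factor(params: "BranchSiteParams") -> float:
    """Common scale so one unit of branch length is one expected
    substitution per codon averaged over site classes (background omegas,
    which govern most of the tree). All classes share this factor, so
    sites in the omega2 class genuinely evolve faster — the rate
    elevation that, together with the dN/dS shift, carries the
    positive-selection signal."""
    props = params.class_proportions()
    bg = [params.omega0, 1.0, params.omega0, 1.0]
    return float(sum(p * mean_substitution_rate(params.kappa, w)
                     for p, w in zip(props, bg)))


def codon_rate_matrix(kappa: float, omega: float,
                      rate_factor: float | None = None) -> np.ndarray:
    """GY-style 61x61 generator with uniform codon frequencies.

    Rates: 0 for multi-nucleotide changes, x kappa for transitions,
    x omega for nonsynonymous changes. Symmetric off-diagonal (uniform
    stationary distribution), rows sum to zero. By default the matrix is
    scaled to mean rate 1; in a site-class mixture pass the shared
    ``rate_factor`` instead so classes keep their relative speeds.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    q = np.where(_SINGLE, 1.0, 0.0)
    q = np.where(_TRANSITION, kappa * q, q)
    q = np.where(_NONSYN, omega * q, q)
    np.fill_diagonal(q, 0.0)
    q /= rate_factor if rate_factor else mean_substitution_rate(kappa, omega)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


from functools import lru_cache


@lru_cache(maxsize=256)
def _eig_unscaled(kappa: float, omega: float):
    """Eigendecomposition of the *unscaled* symmetric generator.

    The rate factor only rescales time, so it is applied at
    exponentiation; caching by (kappa, omega) lets finite-difference
    gradient steps that perturb other parameters reuse the decomposition.
    """
    q = np.where(_SINGLE, 1.0, 0.0)
    q = np.where(_TRANSITION, kappa * q, q)
    q = np.where(_NONSYN, omega * q, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return linalg.eigh(q)


class _TransitionCache:
    """P(t) for one omega via symmetric eigendecomposition of Q."""

    def __init__(self, kappa: float, omega: float,
                 rate_factor: float | None = None):
        if kappa <= 0 or omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        self.eigval, self.eigvec = _eig_unscaled(float(kappa), float(omega))
        self._factor = (rate_factor if rate_factor
                        else mean_substitution_rate(kappa, omega))
        self._memo: dict[float, np.ndarray] = {}

    def prob(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        p = self._memo.get(t)
        if p is None:
            p = (self.eigvec * np.exp(self.eigval * (t / self._factor))) \
                @ self.eigvec.T
            np.clip(p, 0.0, None, out=p)
            self._memo[t] = p
        return p


# ---------------------------------------------------------------------------
# alignment container

@dataclass
class CodonAlignment:
    """Species -> codon-index arrays (gap/stop-free) plus the labeled tree."""

    codons: dict[str, np.ndarray]
    tree: PhyloTree
    foreground: frozenset  # node ids whose parent edge is foreground

    def __post_init__(self):
        lengths = {len(v) for v in self.codons.values()}
        if len(lengths) != 1:
            raise ValueError("unequal codon sequence lengths")
        tips = self.tree.tip_names
        missing = set(self.codons) - tips
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        if set(self.codons) != tips:
            raise ValueError("every tree tip needs a codon sequence")
        known = {n.id for n in self.tree.postorder()}
        bad = set(self.foreground) - known
        if bad:
            raise ValueError(f"unknown foreground nodes: {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.codons.values())))


def codon_alignment_from_strings(seqs: dict[str, str], tree: PhyloTree,
                                 foreground) -> CodonAlignment:
    """Codon-wise aligned CDS strings -> CodonAlignment.

    Columns containing a gap or a stop codon in any species are removed,
    matching the usual pre-filtering for codon-model fitting.
    """
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("aligned CDS must share one length divisible by 3")
    n = next(iter(lengths)) // 3
    cols: dict[str, list[int]] = {sp: [] for sp in seqs}
    for k in range(n):
        codons = {sp: s[3 * k: 3 * k + 3].upper() for sp, s in seqs.items()}
        if any(GAP in c for c in codons.values()):
            continue
        if any(c in _STOPS for c in codons.values()):
            continue
        if any(c not in CODON_INDEX for c in codons.values()):
            raise ValueError(f"unrecognized codon at column {k + 1}")
        for sp, c in codons.items():
            cols[sp].append(CODON_INDEX[c])
    return CodonAlignment(
        codons={sp: np.asarray(v, dtype=np.int64) for sp, v in cols.items()},
        tree=tree, foreground=frozenset(foreground))


def parse_foreground_newick(text: str) -> tuple[PhyloTree, frozenset]:
    """Newick with the ``#1`` foreground-branch suffix convention."""
    tree = read_newick_string(text.replace("#1", "@FG@"))
    fg = set()
    for node in tree.postorder():
        if node.id and node.id.endswith("@FG@"):
            node.id = node.id[: -len("@FG@")].strip() or node.id
            fg.add(node.id)
    return PhyloTree(tree.root), frozenset(fg)


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class BranchSiteParams:
    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    scale: float = 1.0  # global multiplier on input branch lengths

    def __post_init__(self):
        if not (self.kappa > 0 and 0 < self.omega0 <= 1 and self.omega2 >= 1
                and self.p0 >= 0 and self.p1 >= 0
                and self.p0 + self.p1 <= 1 + 1e-12 and self.scale > 0):
            raise ValueError(f"invalid branch-site parameters: {self}")

    def class_proportions(self) -> np.ndarray:
        p01 = self.p0 + self.p1
        rest = max(0.0, 1.0 - p01)
        if p01 <= 0:
            # degenerate: all sites in class 2, split evenly
            return np.array([0.0, 0.0, rest / 2, rest / 2])
        return np.array([
            self.p0, self.p1,
            rest * self.p0 / p01, rest * self.p1 / p01,
        ])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega per class."""
        return [(self.omega0, self.omega0), (1.0, 1.0),
                (self.omega0, self.omega2), (1.0, self.omega2)]


# ---------------------------------------------------------------------------
# pruning likelihood

def _pattern_compress(ca: CodonAlignment):
    species = sorted(ca.codons)
    mat = np.stack([ca.codons[sp] for sp in species])  # (n_sp, n_sites)
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return species, patterns, counts


def _class_loglik(ca: CodonAlignment, species, patterns, kappa, bg_omega,
                  fg_omega, scale, caches) -> np.ndarray:
    """Per-pattern log-likelihood for one site class (uniform root).

    Tip children contribute P[:, observed_codon] directly (a row gather of
    the symmetric P), so dense matmuls are needed only on internal edges.
    """
    npat = patterns.shape[1]
    sp_index = {sp: i for i, sp in enumerate(species)}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for node in ca.tree.postorder():
        if node.is_tip:
            continue
        acc = None
        for child in node.children:
            omega = fg_omega if child.id in ca.foreground else bg_omega
            p = caches[omega].prob(child.length * scale)
            if child.is_tip:
                # one-hot partial: L[p, s] = P(s -> codon_p) = P.T[codon_p, s]
                term = p.T[patterns[sp_index[child.id]]]
            else:
                term = partial.pop(id(child)) @ p  # p symmetric: p == p.T
            acc = term if acc is None else acc * term
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        logscale += np.log(mx)
        partial[id(node)] = acc / mx[:, None]
    root = partial[id(ca.tree.root)]
    return np.log(root.sum(axis=1) / N_CODONS) + logscale


def branch_site_loglik(ca: CodonAlignment, params: BranchSiteParams) -> float:
    """Total log-likelihood of the branch-site mixture (Felsenstein pruning)."""
    species, patterns, counts = _pattern_compress(ca)
    return _loglik_on_patterns(ca, species, patterns, counts, params)


def _loglik_on_patterns(ca, species, patterns, counts,
                        params: BranchSiteParams) -> float:
    factor = mixture_rate_factor(params)
    omegas = {params.omega0, 1.0, params.omega2}
    caches = {w: _TransitionCache(params.kappa, w, factor) for w in omegas}
    props = params.class_proportions()
    lls = []
    for (bg, fg), prop in zip(params.class_omegas(), props):
        if prop <= 0:
            lls.append(None)
            continue
        lls.append(_class_loglik(ca, species, patterns, params.kappa,
                                 bg, fg, params.scale, caches))
    stacked = []
    weights = []
    for ll, prop in zip(lls, props):
        if ll is not None:
            stacked.append(ll + np.log(prop))
            weights.append(prop)
    mat = np.stack(stacked)  # (n_active_classes, npat)
    mx = mat.max(axis=0)
    mix = mx + np.log(np.exp(mat - mx).sum(axis=0))
    return float((mix * counts).sum())


def site_class_posteriors(ca: CodonAlignment,
                          params: BranchSiteParams) -> np.ndarray:
    """Per-site posterior probability of each of the four classes."""
    species, patterns, counts = _pattern_compress(ca)
    factor = mixture_rate_factor(params)
    omegas = {params.omega0, 1.0, params.omega2}
    caches = {w: _TransitionCache(params.kappa, w, factor) for w in omegas}
    props = params.class_proportions()
    lls = np.stack([
        _class_loglik(ca, species, patterns, params.kappa, bg, fg,
                      params.scale, caches)
        for (bg, fg) in params.class_omegas()])
    joint = lls + np.log(np.maximum(props[:, None], 1e-300))
    mx = joint.max(axis=0)
    post = np.exp(joint - mx)
    post /= post.sum(axis=0)
    # expand patterns back to sites
    mat = np.stack([ca.codons[sp] for sp in sorted(ca.codons)])
    _, inverse = np.unique(mat, axis=1, return_inverse=True)
    return post[:, inverse].T


# ---------------------------------------------------------------------------
# fitting

_NULL_STARTS = (
    dict(kappa=2.0, omega0=0.5, s=0.85, r=0.6, scale=1.0),
    dict(kappa=1.0, omega0=0.1, s=0.70, r=0.5, scale=0.5),
    dict(kappa=4.0, omega0=0.9, s=0.95, r=0.8, scale=2.0),
)

_BOUNDS = dict(kappa=(0.05, 50.0), omega0=(1e-4, 1.0), s=(1e-4, 1.0),
               r=(1e-4, 1.0 - 1e-4), scale=(1e-3, 50.0),
               omega2=(1.0, 100.0))


@dataclass
class FitResult:
    params: BranchSiteParams
    lnL: float
    converged: bool
    n_evals: int


def _pack(vec, names, fixed):
    d = dict(zip(names, vec))
    d.update(fixed)
    s, r = d.pop("s"), d.pop("r")
    return BranchSiteParams(kappa=d["kappa"], omega0=d["omega0"],
                            omega2=d.get("omega2", 1.0),
                            p0=s * r, p1=s * (1 - r),
                            scale=d["scale"])


def _fit(ca, names, fixed, starts, maxiter):
    species, patterns, counts = _pattern_compress(ca)
    evals = 0

    def nll(vec):
        nonlocal evals
        evals += 1
        try:
            params = _pack(vec, names, fixed)
        except ValueError:
            return 1e12
        return -_loglik_on_patterns(ca, species, patterns, counts, params)

    best = None
    converged = False
    for start in starts:
        x0 = [start[n] for n in names]
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[_BOUNDS[n] for n in names],
            options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    return FitResult(params=_pack(best.x, names, fixed), lnL=-float(best.fun),
                     converged=converged, n_evals=evals)


def fit_null(ca: CodonAlignment, n_starts: int = 3,
             maxiter: int = 200) -> FitResult:
    """ML fit with omega2 fixed at 1 (neutral foreground class).

    Multi-start from a fixed, documented grid; the global branch-length
    scale is free here and is reused by :func:`fit_alt`.
    """
    starts = list(_NULL_STARTS[:max(1, n_starts)])
    return _fit(ca, ("kappa", "omega0", "s", "r", "scale"),
                {"omega2": 1.0}, starts, maxiter)


def fit_alt(ca: CodonAlignment, null_fit: FitResult | None = None,
            n_starts: int = 3, maxiter: int = 200,
            free_scale: bool = True) -> FitResult:
    """ML fit with omega2 >= 1 free.

    Branch lengths stay proportional to the input tree; by default the
    global rate scale is re-optimized (starting from the null's estimate)
    because pinning it at the null value makes the LRT markedly
    conservative. ``free_scale=False`` reuses the null scale unchanged.
    The first start is the null optimum itself (omega2 = 1), which makes
    lnL_alt >= lnL_null hold by construction up to optimizer tolerance.
    """
    if null_fit is None:
        null_fit = fit_null(ca)
    p = null_fit.params
    s = p.p0 + p.p1
    r = p.p0 / s if s > 0 else 0.5
    base = dict(kappa=p.kappa, omega0=max(p.omega0, 1e-4),
                s=max(s, 1e-4), r=min(max(r, 1e-4), 1 - 1e-4))
    starts = [dict(base, omega2=1.0),
              dict(base, omega2=3.0),
              dict(kappa=2.0, omega0=0.5, s=0.7, r=0.5, omega2=8.0)]
    names = ["kappa", "omega0", "s", "r", "omega2"]
    fixed = {"scale": p.scale}
    if free_scale:
        names.append("scale")
        fixed = {}
        for st in starts:
            st["scale"] = p.scale
    fit = _fit(ca, tuple(names), fixed, starts[:max(1, n_starts)], maxiter)
    if fit.lnL < null_fit.lnL:  # numerical safety net: nested models
        fit = FitResult(params=replace(null_fit.params),
                        lnL=null_fit.lnL, converged=fit.converged,
                        n_evals=fit.n_evals)
    return fit


# ---------------------------------------------------------------------------
# LRT and multiple testing

@dataclass
class LrtResult:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p: float
    p_bh: float | None = None


def lrt(lnL_null: float, lnL_alt: float, df: int = 1) -> LrtResult:
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    return LrtResult(lnL_null=lnL_null, lnL_alt=lnL_alt, statistic=stat,
                     df=df, p=float(stats.chi2.sf(stat, df)))


def bh_adjust(pvals) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    return [float(x) for x in stats.false_discovery_control(arr, method="bh")]


def selection_scan(alignments: dict[str, CodonAlignment],
                   n_starts: int = 3, maxiter: int = 200,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Null/alt fits, LRT and BH adjustment for a set of genes."""
    rows = []
    for gene, ca in alignments.items():
        null = fit_null(ca, n_starts=n_starts, maxiter=maxiter)
        alt = fit_alt(ca, null_fit=null, n_starts=n_starts, maxiter=maxiter)
        res = lrt(null.lnL, alt.lnL)
        rows.append((gene, null.lnL, alt.lnL, res.statistic, res.p,
                     alt.params.omega2, alt.params.kappa,
                     null.converged and alt.converged))
    df = pd.DataFrame(rows, columns=["gene", "lnL_null", "lnL_alt",
                                     "statistic", "p", "omega2_hat",
                                     "kappa_hat", "converged"])
    df["p_bh"] = bh_adjust(df["p"]) if len(df) else []
    df["positive_selection"] = df["p_bh"] < alpha
    return df


# ---------------------------------------------------------------------------
# simulation under the branch-site model (for calibration and power)

def simulate_codon_alignment(tree: PhyloTree, foreground,
                             params: BranchSiteParams, n_codons: int,
                             rng: np.random.Generator) -> CodonAlignment:
    """Evolve codon sites down the tree under the branch-site mixture."""
    foreground = frozenset(foreground)
    props = params.class_proportions()
    classes = rng.choice(4, size=n_codons, p=props / props.sum())
    omega_pairs = params.class_omegas()
    factor = mixture_rate_factor(params)
    omegas = {w for pair in omega_pairs for w in pair}
    caches = {w: _TransitionCache(params.kappa, w, factor) for w in omegas}

    states = {id(tree.root): rng.integers(0, N_CODONS, size=n_codons)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        for cls in range(4):
            mask = classes == cls
            if not mask.any():
                continue
            bg, fg = omega_pairs[cls]
            omega = fg if node.id in foreground else bg
            p = caches[omega].prob(node.length * params.scale)
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child_states[mask] = (rows > u[:, None]).argmax(axis=1)
        states[id(node)] = child_states
    codons = {n.id: states[id(n)] for n in tree.postorder() if n.is_tip}
    return CodonAlignment(codons=codons, tree=tree, foreground=foreground)
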