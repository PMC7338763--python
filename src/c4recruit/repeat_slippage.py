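"""Lineage-specific tandem-repeat insertions and slipped-strand mispairing.

The detector is alignment-anchored: an insertion is a maximal run of
columns occupied by a proper subset of species (the carriers) and gapped in
everyone else. Within each carrier's inserted segment the best (unit
length, copy count) decomposition is chosen by exhaustive search over unit
lengths and phases, maximizing covered residues with ties to the smallest
unit.

Slippage evidence combines three signals classically associated with
slipped-strand mispairing: an ancestral single element adjacent to the
insertion that seeded the expansion, a direct repeat shared by the head and
tail of the seed's coding DNA, and the capacity of that DNA to fold back
on itself (scored by Nussinov maximum base pairing).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict

from .seq_core import GAP, Alignment, OrthologSet


@dataclass
class RepeatInsertion:
    carrier_species: list[str]
    insertion_column_span: tuple[int, int]  # 1-based inclusive
    unit_length_aa: int
    copies: dict[str, int]  # per carrier
    consensus_unit: str
    variant_sites: list[tuple[int, str]]  # (1-based unit position, states)
    total_span_aa: dict[str, int]  # copies * unit_length per carrier
    repetitive: bool = True
    carrier_segments: dict[str, str] = field(default_factory=dict)


@dataclass
class SlippageEvidence:
    ancestral_unit: str | None = None
    ancestral_unit_length: int = 0
    ancestral_unit_relation: str | None = None
    flank_repeat_seq: str = ""
    flank_repeat_len_bp: int = 0
    hairpin_pairs: int = -1
    hairpin_capable: bool | None = None
    hairpin_structure: str = ""


# ---------------------------------------------------------------------------
# tandem insertion detection

def _insertion_spans(aln: Alignment) -> list[tuple[int, int, set[str]]]:
    """Maximal runs of columns occupied by a proper subset of species."""
    n_species = len(aln.records)
    spans: list[tuple[int, int, set[str]]] = []
    start = None
    for col in range(1, aln.n_cols + 2):
        if col <= aln.n_cols:
            states = aln.column(col)
            carriers = {s for s, x in states.items() if x != GAP}
            is_ins = 0 < len(carriers) < n_species
        else:
            is_ins = False
        if is_ins and start is None:
            start = col
        elif not is_ins and start is not None:
            span_carriers = set()
            for c in range(start, col):
                span_carriers |= {s for s, x in aln.column(c).items() if x != GAP}
            spans.append((start, col - 1, span_carriers))
            start = None
    return spans


def _best_decomposition(seq: str, unit: int,
                        max_mismatch_per_copy: int) -> tuple[int, int] | None:
    """Best (offset, copies) of *unit*-length tandem copies in *seq*.

    Copies must each sit within ``max_mismatch_per_copy`` of their own
    positionwise-majority consensus. Returns None when no phase admits
    at least two valid copies.
    """
    n = len(seq)
    k_full = n // unit
    if k_full < 2:
        return None
    best: tuple[int, int] | None = None
    for k in range(k_full, 1, -1):
        for offset in range(0, n - k * unit + 1):
            copies = [seq[offset + i * unit: offset + (i + 1) * unit]
                      for i in range(k)]
            consensus = _consensus(copies)
            if all(_hamming(c, consensus) <= max_mismatch_per_copy
                   for c in copies):
                if best is None:
                    best = (offset, k)
                break
        if best is not None:
            break
    return best


def _consensus(copies: list[str]) -> str:
    out = []
    for pos in range(len(copies[0])):
        counts = Counter(c[pos] for c in copies)
        top = max(counts.values())
        out.append(min(s for s, n in counts.items() if n == top))
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def detect_tandem_insertion(source, min_unit: int = 3, max_unit: int = 50,
                            max_mismatch_per_copy: int = 2,
                            ) -> list[RepeatInsertion]:
    """Find lineage-specific insertions and their tandem-repeat structure.

    For each insertion span, unit lengths from ``min_unit`` to ``max_unit``
    are scanned; the unit maximizing the total residues covered by valid
    copies across carriers wins, ties resolved toward the smallest unit.
    Spans shorter than two minimal units are reported with
    ``repetitive=False`` and a single copy of the whole segment.
    """
    aln = source.protein_alignment if isinstance(source, OrthologSet) else source
    out: list[RepeatInsertion] = []
    for start, end, carriers in _insertion_spans(aln):
        segments = {}
        for sp in sorted(carriers):
            row = aln.by_species(sp).residues[start - 1:end]
            segments[sp] = row.replace(GAP, "")
        max_seg = max(len(s) for s in segments.values())
        if max_seg < 2 * min_unit:
            out.append(RepeatInsertion(
                carrier_species=sorted(carriers),
                insertion_column_span=(start, end),
                unit_length_aa=max_seg,
                copies={sp: 1 for sp in segments},
                consensus_unit=max(segments.values(), key=len),
                variant_sites=[],
                total_span_aa={sp: len(s) for sp, s in segments.items()},
                repetitive=False,
                carrier_segments=segments,
            ))
            continue

        best_unit, best_cover, best_plan = None, -1, None
        for unit in range(min_unit, min(max_unit, max_seg // 2) + 1):
            plan = {}
            cover = 0
            ok = True
            for sp, seq in segments.items():
                dec = _best_decomposition(seq, unit, max_mismatch_per_copy)
                if dec is None:
                    ok = False
                    break
                plan[sp] = dec
                cover += dec[1] * unit
            if ok and cover > best_cover:
                best_unit, best_cover, best_plan = unit, cover, plan
        if best_unit is None:
            out.append(RepeatInsertion(
                carrier_species=sorted(carriers),
                insertion_column_span=(start, end),
                unit_length_aa=max_seg,
                copies={sp: 1 for sp in segments},
                consensus_unit=max(segments.values(), key=len),
                variant_sites=[],
                total_span_aa={sp: len(s) for sp, s in segments.items()},
                repetitive=False,
                carrier_segments=segments,
            ))
            continue

        all_copies: list[str] = []
        copies = {}
        for sp, seq in segments.items():
            offset, k = best_plan[sp]
            copies[sp] = k
            all_copies.extend(seq[offset + i * best_unit:
                                  offset + (i + 1) * best_unit]
                              for i in range(k))
        consensus = _consensus(all_copies)
        variants = []
        for pos in range(best_unit):
            states = sorted({c[pos] for c in all_copies})
            if len(states) > 1:
                variants.append((pos + 1, "".join(states)))
        out.append(RepeatInsertion(
            carrier_species=sorted(carriers),
            insertion_column_span=(start, end),
            unit_length_aa=best_unit,
            copies=copies,
            consensus_unit=consensus,
            variant_sites=variants,
            total_span_aa={sp: k * best_unit for sp, k in copies.items()},
            repetitive=True,
            carrier_segments=segments,
        ))
    return out


# ---------------------------------------------------------------------------
# ancestral element

def infer_ancestral_unit(source, insertion: RepeatInsertion,
                         max_mismatch: int = 0) -> SlippageEvidence:
    """Single element adjacent to the insertion's N-terminal boundary.

    Looks for the longest block of columns immediately upstream of the span
    that is fixed across *all* species and matches a suffix of the
    consensus unit (within ``max_mismatch``). The Fig-style signature is an
    element one residue shorter than the unit, i.e. the expansion seed.
    """
    aln = source.protein_alignment if isinstance(source, OrthologSet) else source
    start = insertion.insertion_column_span[0]
    unit = insertion.consensus_unit
    u = len(unit)
    for m in range(u, 0, -1):
        first = start - m
        if first < 1:
            continue
        cols = [aln.column(c) for c in range(first, start)]
        if any(len(set(col.values())) != 1 or GAP in col.values()
               for col in cols):
            continue
        elem = "".join(next(iter(col.values())) for col in cols)
        if _hamming(elem, unit[u - m:]) <= max_mismatch:
            relation = ("identical to consensus unit" if m == u else
                        f"consensus unit minus {u - m} N-terminal residue(s)")
            return SlippageEvidence(ancestral_unit=elem,
                                    ancestral_unit_length=m,
                                    ancestral_unit_relation=relation)
    return SlippageEvidence(ancestral_unit=None, ancestral_unit_length=0)


# ---------------------------------------------------------------------------
# flanking direct repeats

def find_flanking_direct_repeats(cds_region: str,
                                 max_len: int = 30) -> tuple[str, int]:
    """Longest DNA word at both the head and the tail of the region.

    Head and tail occurrences may not overlap, so the repeat length is
    capped at half the region. Returns ("", 0) when nothing is shared.
    """
    region = cds_region.upper()
    limit = min(max_len, len(region) // 2)
    for L in range(limit, 0, -1):
        if region[:L] == region[-L:]:
            return region[:L], L
    return "", 0


# ---------------------------------------------------------------------------
# Nussinov maximum base pairing

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def nussinov_hairpin(dna: str, min_loop: int = 3, allow_gu: bool = True,
                     capable_threshold: int | None = None,
                     ) -> tuple[int, str, bool]:
    """Maximum base pairing (Nussinov DP) and one optimal structure.

    DNA is treated as a transcript proxy: Watson–Crick pairs plus G·T
    wobble by default. ``hairpin_capable`` is True when the optimum meets
    ``capable_threshold`` (default ceil(len/6)) — an artifact-level
    structural-capacity call, not a thermodynamic prediction.
    """
    seq = dna.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    n = len(seq)
    pairs = _PAIRS | _WOBBLE if allow_gu else _PAIRS

    def can_pair(i, j):
        return (seq[i], seq[j]) in pairs

    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(k, j):
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + 1 + (dp[k + 1][j - 1] if k + 1 <= j - 1 else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best
    max_pairs = dp[0][n - 1] if n else 0

    structure = ["."] * n

    def trace(i, j):
        if j - i <= min_loop:
            return
        if dp[i][j] == dp[i][j - 1]:
            trace(i, j - 1)
            return
        for k in range(i, j - min_loop):
            if can_pair(k, j):
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == dp[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        trace(i, k - 1)
                    if k + 1 <= j - 1:
                        trace(k + 1, j - 1)
                    return
        trace(i, j - 1)  # pragma: no cover - defensive

    if n:
        trace(0, n - 1)
    threshold = capable_threshold if capable_threshold is not None \
        else math.ceil(n / 6)
    return max_pairs, "".join(structure), max_pairs >= threshold


# ---------------------------------------------------------------------------
# CDS coordinate helper and report

def segment_cds(oset: OrthologSet, species: str, start_col: int,
                end_col: int) -> str:
    """CDS slice of a species covering alignment columns (1-based incl.)."""
    rec = oset.protein_alignment.by_species(species)
    cds = oset.cds[species].ungapped
    # map columns to ungapped protein positions
    pos = 0
    first_aa = last_aa = None
    for col, ch in enumerate(rec.residues, start=1):
        if ch == GAP:
            continue
        pos += 1
        if col >= start_col and first_aa is None:
            first_aa = pos
        if col <= end_col:
            last_aa = pos
    if first_aa is None or last_aa is None or last_aa < first_aa:
        raise ValueError(
            f"species {species!r} has no residues in columns "
            f"{start_col}..{end_col}")
    return cds[(first_aa - 1) * 3: last_aa * 3]


def slippage_report(insertion: RepeatInsertion,
                    evidence: SlippageEvidence,
                    origin_node: str | None = None) -> dict:
    """JSON-ready narrative record tying the insertion to its evidence."""
    rec = {
        "insertion": asdict(insertion),
        "evidence": asdict(evidence),
        "origin_node": origin_node,
        "interpretation": None,
    }
    if (insertion.repetitive and evidence.flank_repeat_len_bp > 0
            and evidence.hairpin_capable):
        rec["interpretation"] = (
            "tandem expansion consistent with slipped-strand mispairing: "
            f"{insertion.unit_length_aa}-aa unit, flanking direct repeat "
            f"{evidence.flank_repeat_seq!r}, hairpin-capable template")
    return json.loads(json.dumps(rec))  # guarantee JSON round-trip
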