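"""Promoter cis-element scanning and conserved-block comparison.

Promoters are given on the coding strand with their 3' end abutting the A
of the start codon; positions are reported as 1-based negative offsets
(offset −1 = the base immediately upstream of ATG), the convention used
when quoting element positions like "−2,783 to −2,740 bp from the start
codon".

The built-in library ships the MEM1 B submodule core, the 15-mer whose
tandem duplication marks mesophyll-specific expression modules of C4
Flaveria genes; "submodule present" means at least two core copies within
a short window, mirroring the two-copies-in-44-bp geometry of the module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .seq_core import SeqRecord, global_identity

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Motif:
    id: str
    sequence: str  # IUPAC string
    description: str = ""

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.id!r}: non-IUPAC {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif_id: str
    offset: int  # signed, start of the match; -1 = base next to ATG
    end_offset: int  # signed, last base of the match
    strand: str
    mismatches: int


@dataclass(frozen=True)
class PromoterBlock:
    a_start_offset: int
    a_end_offset: int
    b_start_offset: int
    b_end_offset: int
    length: int
    identity: float


# ---------------------------------------------------------------------------
# coordinate conversion (tested round-trip)

def offset_to_index(offset: int, promoter_len: int) -> int:
    """Signed upstream offset -> 0-based index into the promoter string."""
    if offset > -1:
        raise ValueError("promoter offsets are <= -1 (upstream of ATG)")
    idx = promoter_len + offset
    if idx < 0:
        raise ValueError(f"offset {offset} outside promoter of length {promoter_len}")
    return idx


def index_to_offset(index: int, promoter_len: int) -> int:
    if not 0 <= index < promoter_len:
        raise ValueError(f"index {index} outside promoter")
    return index - promoter_len


# ---------------------------------------------------------------------------
# scanning

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _matches(window: str, motif: str, max_mismatch: int) -> int | None:
    mm = 0
    for w, m in zip(window, motif):
        if w not in IUPAC[m]:
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def scan_motif(promoter, motif, max_mismatch: int = 0,
               scan_revcomp: bool = False) -> list[MotifHit]:
    """All matches of an IUPAC motif in a promoter, coding strand.

    A motif longer than the promoter yields an empty list. With
    ``scan_revcomp`` the reverse-complement of the motif is also scanned
    (hits still reported in promoter coordinates, strand "-").
    """
    if isinstance(promoter, SeqRecord):
        seq, pid = promoter.residues.upper(), promoter.id
    else:
        seq, pid = str(promoter).upper(), "promoter"
    if isinstance(motif, Motif):
        pattern, mid = motif.sequence.upper(), motif.id
    else:
        pattern, mid = str(motif).upper(), "motif"
        Motif(mid, pattern)  # validates IUPAC characters
    L, m = len(seq), len(pattern)
    hits: list[MotifHit] = []
    patterns = [(pattern, "+")]
    if scan_revcomp:
        patterns.append((pattern.translate(_COMPLEMENT)[::-1], "-"))
    for pat, strand in patterns:
        for i in range(0, L - m + 1):
            mm = _matches(seq[i:i + m], pat, max_mismatch)
            if mm is not None:
                hits.append(MotifHit(
                    promoter_id=pid, motif_id=mid,
                    offset=index_to_offset(i, L),
                    end_offset=index_to_offset(i + m - 1, L),
                    strand=strand, mismatches=mm))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def submodule_present(promoter, core, window: int = 60,
                      max_mismatch: int = 0, min_copies: int = 2) -> bool:
    """True when >= min_copies core hits start within one *window* bp span."""
    hits = scan_motif(promoter, core, max_mismatch=max_mismatch)
    starts = [h.offset for h in hits]
    for i in range(len(starts)):
        n = sum(1 for s in starts[i:] if s - starts[i] < window)
        if n >= min_copies:
            return True
    return False


# ---------------------------------------------------------------------------
# promoter identity and conserved blocks

def promoter_identity(a, b, match: float = 1.0, mismatch: float = 0.0,
                      gap: float = -1.0) -> float:
    """Global (Needleman–Wunsch) percent identity between two promoters."""
    return global_identity(a, b, match=match, mismatch=mismatch, gap=gap)


def find_conserved_blocks(a, b, window: int = 50, min_identity: float = 70.0,
                          seed: int = 12, max_gap: int | None = None,
                          ) -> list[PromoterBlock]:
    """Near-identical ungapped blocks shared by two promoters.

    Exact ``seed``-mers on a common diagonal are chained (gaps up to
    ``max_gap``, default = window) and each chained run is kept when it is
    at least ``window`` bp long and at least ``min_identity`` percent
    identical. Blocks are non-overlapping within each promoter (longest
    kept first). Detection is seed-limited: a region with no exact
    seed-mer cannot be reported, which is the intended behavior for
    promoter-scale comparisons.
    """
    sa = (a.residues if isinstance(a, SeqRecord) else str(a)).upper()
    sb = (b.residues if isinstance(b, SeqRecord) else str(b)).upper()
    if max_gap is None:
        max_gap = window
    index: dict[str, list[int]] = {}
    for j in range(len(sb) - seed + 1):
        index.setdefault(sb[j:j + seed], []).append(j)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(sa) - seed + 1):
        for j in index.get(sa[i:i + seed], ()):
            by_diag.setdefault(j - i, []).append(i)

    candidates: list[PromoterBlock] = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        runs = []
        for i in starts[1:]:
            if i - prev <= max_gap:
                prev = i
            else:
                runs.append((run_start, prev + seed))
                run_start = prev = i
        runs.append((run_start, prev + seed))
        for lo, hi in runs:
            length = hi - lo
            if length < window:
                continue
            seg_a = sa[lo:hi]
            seg_b = sb[lo + diag:hi + diag]
            ident = 100.0 * sum(x == y for x, y in zip(seg_a, seg_b)) / length
            if ident < min_identity:
                continue
            candidates.append(PromoterBlock(
                a_start_offset=index_to_offset(lo, len(sa)),
                a_end_offset=index_to_offset(hi - 1, len(sa)),
                b_start_offset=index_to_offset(lo + diag, len(sb)),
                b_end_offset=index_to_offset(hi + diag - 1, len(sb)),
                length=length, identity=round(ident, 2)))

    candidates.sort(key=lambda blk: (-blk.length, blk.a_start_offset))
    kept: list[PromoterBlock] = []
    for blk in candidates:
        clash = any(
            not (blk.a_end_offset < k.a_start_offset or blk.a_start_offset > k.a_end_offset)
            or not (blk.b_end_offset < k.b_start_offset or blk.b_start_offset > k.b_end_offset)
            for k in kept)
        if not clash:
            kept.append(blk)
    kept.sort(key=lambda blk: blk.a_start_offset)
    return kept


# ---------------------------------------------------------------------------
# motif library

MEM1_B_CORE = Motif(
    "MEM1_B_core", "AAAACAAACAAAAAC",
    "Core 15-mer of the MEM1 B submodule; two tandem copies within ~44 bp "
    "mark the mesophyll expression module of C4 Flaveria promoters.")


def builtin_motifs() -> dict[str, Motif]:
    return {MEM1_B_CORE.id: MEM1_B_CORE}


def get_motif(motif_id: str, library: dict[str, Motif] | None = None) -> Motif:
    lib = library if library is not None else builtin_motifs()
    if motif_id not in lib:
        raise KeyError(f"unknown motif {motif_id!r}; have {sorted(lib)}")
    return lib[motif_id]


def load_motifs_tsv(path) -> dict[str, Motif]:
    out = dict(builtin_motifs())
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"id", "sequence"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ValueError(f"{path}: motif TSV needs columns {sorted(need)}")
        for row in reader:
            out[row["id"]] = Motif(row["id"], row["sequence"].upper(),
                                   row.get("description", "") or "")
    return out


def write_motifs_tsv(motifs: dict[str, Motif], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "sequence", "description"])
        for m in motifs.values():
            w.writerow([m.id, m.sequence, m.description])
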