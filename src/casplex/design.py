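"""crRNA and RPA-primer design rules for allele discrimination.

Spacers are the reverse complement of their target window: 28 nt for
LwaCas13a, 30 nt for PsmCas13b, 20 nt for LbaCas12a. LwaCas13a and
LbaCas12a constructs carry the direct repeat (DR) 5' of the spacer,
PsmCas13b 3' of it; spacer positions are numbered 1-based from the
DR-proximal end. SNP-discriminating designs place the SNP at spacer
position 3 and add one or two synthetic mismatches at positions
{1,2,4,5} — a deliberate spacer-target mismatch near the SNP so the extra
SNP mismatch on the non-target allele abolishes collateral activity.
Deletion-sensing designs tile 30-nt wild-type spacers across the TTATAA
hexamer in 1-nt steps. Cas12a designs require a PAM from
{TTTV, TCTV, TTCV, CTTV}.

RPA primers: 25-30 nt cores, nearest-neighbor Tm in 57-67 degC
(SantaLucia unified parameters at 50 mM Na+, 250 nM oligo), forward
primer 5' of both variants with a T7 promoter overhang, reverse 3' of
both, so a single amplicon covers both variant coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

from Bio.SeqUtils import MeltingTemp as _mt

SPACER_LENGTH = {"LwaCas13a": 28, "PsmCas13b": 30, "LbaCas12a": 20}
DR_END = {"LwaCas13a": "5p", "PsmCas13b": "3p", "LbaCas12a": "5p"}

#: standard T7 promoter overhang for forward RPA primers
T7_OVERHANG = "TAATACGACTCACTATAGGG"

PAM_MOTIFS = ("TTTV", "TCTV", "TTCV", "CTTV")

_DNA_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
#: RNA base complementary to a DNA template base
_RNA_COMP = {"A": "U", "C": "G", "G": "C", "T": "A"}
#: synthetic-mismatch substitution: the transversion partner of the
#: correct spacer base (purine <-> pyrimidine, never the complement)
_MISMATCH_SUB = {"A": "C", "C": "A", "G": "U", "U": "G"}

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "V": "ACG", "N": "ACGT"}


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    """RNA reverse complement of a DNA target window (5'->3')."""
    return "".join(_RNA_COMP[b] for b in seq.upper())[::-1]


@dataclass(frozen=True)
class CrRNADesign:
    """One crRNA candidate."""

    enzyme: str
    spacer: str                        # RNA alphabet, 5'->3'
    dr_end: str                        # '5p' or '3p'
    target_window: tuple[int, int]     # 0-based half-open on template
    variant_offset: int | None         # 1-based spacer position, DR-proximal
    mismatch_positions: tuple[int, ...]  # same convention
    pam: str | None = None             # Cas12a only
    allele: str = "mutant"             # which allele the spacer senses

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH[self.enzyme]:
            raise ValueError(f"{self.enzyme} spacer must be "
                             f"{SPACER_LENGTH[self.enzyme]} nt, got {len(self.spacer)}")
        if set(self.spacer) - set("ACGU"):
            raise ValueError("spacer must be RNA alphabet (ACGU)")

    def spacer_index(self, position: int) -> int:
        """0-based spacer string index of a 1-based DR-proximal position."""
        if self.dr_end == "5p":
            return position - 1
        return len(self.spacer) - position

    def template_coord(self, position: int) -> int:
        """Template coordinate targeted by a 1-based spacer position."""
        a, b = self.target_window
        # spacer is revcomp of the window: spacer string index i pairs with
        # template coordinate b-1-i
        return b - 1 - self.spacer_index(position)


def _check_flanks(template: str, start: int, end: int, what: str) -> None:
    if start < 0 or end > len(template):
        raise ValueError(f"insufficient flanking sequence for {what}: "
                         f"window [{start},{end}) outside template of length {len(template)}")


# ---------------------------------------------------------------------------
# SNP-discriminating crRNAs


def design_snp_crrnas(template: str, snp_pos: int, enzyme: str = "LwaCas13a",
                      mismatch_strategy: str = "one_and_two",
                      mutant_base: str = "G") -> list[CrRNADesign]:
    """Mutant-sensing spacers with the SNP at position 3 and synthetic
    mismatches near it.

    Candidates carry every singleton and pair of mismatches from
    positions {1,2,4,5} (position 3 is the SNP itself); the {1,4} pair —
    the geometry with the best target/non-target discrimination — is
    always among them. Each mismatch substitutes the transversion partner
    of the correct base, which pairs with neither allele.
    """
    template = template.upper()
    L = SPACER_LENGTH[enzyme]
    if DR_END[enzyme] != "5p":
        raise ValueError("SNP designs are defined for 5'-DR enzymes")
    # position 3 (DR-proximal) must sit on the SNP: spacer index 2 pairs
    # with template coordinate end-3, so end = snp_pos + 3
    end = snp_pos + 3
    start = end - L
    _check_flanks(template, start, end, "SNP spacer")
    window = template[start:end]
    mutant_window = window[:L - 3] + mutant_base + window[L - 2:]
    base_spacer = revcomp_rna(mutant_window)

    if mismatch_strategy == "one_and_two":
        pos_sets = [*({p} for p in (1, 2, 4, 5)),
                    *(set(c) for c in combinations((1, 2, 4, 5), 2))]
    elif mismatch_strategy == "none":
        pos_sets = [set()]
    else:
        raise ValueError(f"unknown mismatch strategy {mismatch_strategy!r}")

    designs = []
    for mismatches in pos_sets:
        spacer = list(base_spacer)
        for p in sorted(mismatches):
            i = p - 1   # 5'-DR: position 1 is spacer index 0
            spacer[i] = _MISMATCH_SUB[spacer[i]]
        designs.append(CrRNADesign(
            enzyme=enzyme, spacer="".join(spacer), dr_end=DR_END[enzyme],
            target_window=(start, end), variant_offset=3,
            mismatch_positions=tuple(sorted(mismatches)), allele="mutant"))
    return designs


# ---------------------------------------------------------------------------
# deletion-tiling crRNAs


def design_deletion_tiling(template: str, del_interval: tuple[int, int],
                           enzyme: str = "PsmCas13b",
                           mode: str = "full") -> list[CrRNADesign]:
    """Wild-type-sensing spacers tiled in 1-nt steps across a deletion.

    mode='full': every window fully contains the deleted bases (a 6-nt
    target and 30-nt spacer give 25 designs). mode='partial': any window
    overlapping the deletion by >=1 base.
    """
    template = template.upper()
    a, b = del_interval
    if not (0 <= a < b <= len(template)):
        raise ValueError(f"deletion interval {del_interval} outside template")
    L = SPACER_LENGTH[enzyme]
    if mode == "full":
        starts = range(b - L, a + 1)
    elif mode == "partial":
        starts = range(a - L + 1, b)
    else:
        raise ValueError(f"unknown tiling mode {mode!r}")
    designs = []
    for s in starts:
        _check_flanks(template, s, s + L, "deletion tiling spacer")
        window = template[s:s + L]
        designs.append(CrRNADesign(
            enzyme=enzyme, spacer=revcomp_rna(window), dr_end=DR_END[enzyme],
            target_window=(s, s + L), variant_offset=None,
            mismatch_positions=(), allele="wt"))
    return designs


# ---------------------------------------------------------------------------
# PAM scan


@dataclass(frozen=True)
class PamSite:
    """A PAM motif hit: forward-strand coordinates, 0-based half-open."""

    start: int
    end: int
    strand: str     # '+' or '-'
    motif: str
    sequence: str   # as read on the motif's own strand


def _matches(seq: str, motif: str) -> bool:
    return len(seq) == len(motif) and all(b in _IUPAC[m] for b, m in zip(seq, motif))


def scan_pam(template: str, motifs=PAM_MOTIFS, strand: str = "both") -> list[PamSite]:
    """All PAM motif matches on the requested strand(s).

    Minus-strand hits are reported in forward coordinates (the interval
    whose reverse complement reads the motif). V = A/C/G.
    """
    template = template.upper()
    sites: list[PamSite] = []
    want_plus = strand in ("+", "both")
    want_minus = strand in ("-", "both")
    for motif in motifs:
        k = len(motif)
        for i in range(len(template) - k + 1):
            word = template[i:i + k]
            if want_plus and _matches(word, motif):
                sites.append(PamSite(i, i + k, "+", motif, word))
            if want_minus and _matches(revcomp_dna(word), motif):
                sites.append(PamSite(i, i + k, "-", motif, revcomp_dna(word)))
    sites.sort(key=lambda s: (s.start, s.strand, s.motif))
    return sites


def design_cas12a_crrnas(template: str, variant, strand: str = "both",
                         allele: str = "mutant") -> list[CrRNADesign]:
    """PAM-anchored 20-nt LbaCas12a spacers overlapping a variant.

    Scans canonical and non-canonical PAMs ({TTTV, TCTV, TTCV, CTTV}) on
    both strands and emits a design for every PAM whose adjacent 20-nt
    protospacer covers the variant (a position or a half-open interval).
    The spacer is the reverse complement of the protospacer window as read
    on the PAM's strand.
    """
    template = template.upper()
    if isinstance(variant, (tuple, list)):
        v_start, v_end = int(variant[0]), int(variant[1])
    else:
        v_start, v_end = int(variant), int(variant) + 1
    L = SPACER_LENGTH["LbaCas12a"]
    designs = []
    for site in scan_pam(template, strand=strand):
        if site.strand == "+":
            w = (site.end, site.end + L)
            if w[1] > len(template):
                continue
            window = template[w[0]:w[1]]
        else:
            w = (site.start - L, site.start)
            if w[0] < 0:
                continue
            window = revcomp_dna(template[w[0]:w[1]])
        if w[1] <= v_start or w[0] >= v_end:   # protospacer must cover the variant
            continue
        designs.append(CrRNADesign(
            enzyme="LbaCas12a", spacer=revcomp_rna(window), dr_end="5p",
            target_window=w, variant_offset=None, mismatch_positions=(),
            pam=site.sequence, allele=allele))
    return designs


# ---------------------------------------------------------------------------
# RPA primers


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse RPA primer pair and its amplicon."""

    forward: str                       # core, 5'->3' (no overhang)
    reverse: str                       # 5'->3' on the minus strand
    forward_full: str                  # overhang + core
    t7_overhang: bool
    tm_forward: float                  # degC, core only
    tm_reverse: float
    amplicon: tuple[int, int]          # 0-based half-open on template
    amplicon_length: int


def primer_tm(seq: str, Na: float = 50.0, dnac1: float = 250.0) -> float:
    """Nearest-neighbor melting temperature (degC).

    SantaLucia unified parameters at 50 mM monovalent salt and 250 nM
    oligo (the design model used throughout this module).
    """
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=Na, dnac1=dnac1,
                           dnac2=0, saltcorr=5))


def design_rpa_primers(template: str, targets, len_range=(25, 30),
                       tm_range=(57.0, 67.0), t7_overhang: bool = True,
                       search_span: int = 60,
                       max_pairs: int | None = 20) -> list[PrimerPair]:
    """Enumerate primer pairs whose amplicon spans all target coordinates.

    ``targets`` is a list of 0-based positions and/or (start, end)
    half-open intervals. Forward cores end at or before the leftmost
    target and start within ``search_span`` nt of it; reverse cores
    mirror this on the 3' side. Pairs are returned sorted by the
    forward/reverse Tm difference; an empty list means no feasible pair
    under the constraints.
    """
    template = template.upper()
    coords: list[int] = []
    for t in targets:
        if isinstance(t, (tuple, list)):
            coords.extend([int(t[0]), int(t[1])])
        else:
            coords.append(int(t))
    if not coords:
        raise ValueError("need at least one target coordinate")
    left, right = min(coords), max(coords)
    lmin, lmax = len_range

    def candidates(region_start: int, region_end: int):
        out = []
        for start in range(max(0, region_start), region_end):
            for L in range(lmin, lmax + 1):
                end = start + L
                if end > region_end:
                    break
                core = template[start:end]
                tm = primer_tm(core)
                if tm_range[0] <= tm <= tm_range[1]:
                    out.append((start, end, core, tm))
        return out

    fwd = candidates(left - search_span - lmax, left)
    rev_windows = candidates(right, min(len(template), right + search_span + lmax))
    pairs = []
    for fs, fe, fcore, ftm in fwd:
        for rs, re_, rwin, rtm_ in rev_windows:
            rcore = revcomp_dna(rwin)
            pairs.append(PrimerPair(
                forward=fcore, reverse=rcore,
                forward_full=(T7_OVERHANG + fcore) if t7_overhang else fcore,
                t7_overhang=t7_overhang, tm_forward=ftm, tm_reverse=rtm_,
                amplicon=(fs, re_), amplicon_length=re_ - fs))
    pairs.sort(key=lambda p: (abs(p.tm_forward - p.tm_reverse), p.amplicon_length))
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return pairs


def designs_frame(designs) -> "object":
    """Candidate list (crRNAs or primer pairs) as a DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for d in designs:
        if isinstance(d, CrRNADesign):
            rows.append({
                "kind": "crRNA", "enzyme": d.enzyme, "spacer": d.spacer,
                "dr_end": d.dr_end, "target_start": d.target_window[0],
                "target_end": d.target_window[1],
                "variant_offset": d.variant_offset,
                "mismatch_positions": ",".join(map(str, d.mismatch_positions)),
                "pam": d.pam or "", "allele": d.allele,
            })
        elif isinstance(d, PrimerPair):
            rows.append({
                "kind": "primer_pair", "forward": d.forward_full,
                "reverse": d.reverse, "tm_forward": round(d.tm_forward, 2),
                "tm_reverse": round(d.tm_reverse, 2),
                "amplicon_start": d.amplicon[0], "amplicon_end": d.amplicon[1],
                "amplicon_length": d.amplicon_length,
            })
        else:
            raise TypeError(f"cannot tabulate {type(d)}")
    return pd.DataFrame(rows)
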