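"""Threshold-based genotype calling from score triples.

The FAM score (LwaCas13a, G1 mutant sensing) is trichotomized — below 0.2
wild-type, 0.2-0.8 heterozygous (closed interval), above 0.8 homozygous —
and the HEX (LbaCas12a, G2 mutant) and TEX (PsmCas13b, G2 wild-type)
scores are dichotomized at 0.05 (strictly below = low). The resulting
level triple maps through a decision table onto the six genotypes; the
six valid triples are exactly those consistent with two alleles. Samples
whose scores sit below every lowest threshold, or whose triple matches no
genotype, are INVALID — the assay's integrated QC.

Thresholds are configuration, not constants: deployments on other readers
may need re-tuned values, so :class:`ThresholdSet` can be loaded from a
key-value text file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alleles import GENOTYPES


@dataclass(frozen=True)
class ThresholdSet:
    """Score thresholds (unitless); defaults are the assay's published values."""

    fam_lo: float = 0.2
    fam_hi: float = 0.8
    hex_lo: float = 0.05
    tex_lo: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fam_lo < self.fam_hi):
            raise ValueError("need 0 < fam_lo < fam_hi")
        if self.hex_lo <= 0 or self.tex_lo <= 0:
            raise ValueError("hex_lo and tex_lo must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdSet":
        """Load from a `key = value` / `key: value` text file (or YAML)."""
        import yaml

        text = Path(path).read_text(encoding="utf-8").replace("=", ":")
        data = yaml.safe_load(text) or {}
        known = {k: float(v) for k, v in data.items()
                 if k in ("fam_lo", "fam_hi", "hex_lo", "tex_lo")}
        return cls(**known)


#: level triple (fam, hex, tex) -> genotype; the six allele-consistent rows
DECISION_TABLE: dict[tuple[str, str, str], str] = {
    ("wt", "low", "high"): "G0G0",
    ("het", "low", "high"): "G0G1",
    ("hom", "low", "high"): "G1G1",
    ("wt", "high", "high"): "G0G2",
    ("het", "high", "high"): "G1G2",
    ("wt", "high", "low"): "G2G2",
}


def classify_levels(scores: dict[str, float],
                    th: ThresholdSet | None = None) -> tuple[str, str, str]:
    """Score triple -> qualitative level triple (fam, hex, tex).

    Boundary convention: the heterozygous FAM interval is closed
    ([fam_lo, fam_hi]); HEX/TEX are 'low' strictly below their threshold.
    """
    th = th or ThresholdSet()
    s_fam, s_hex, s_tex = scores["FAM"], scores["HEX"], scores["TEX"]
    for name, v in (("FAM", s_fam), ("HEX", s_hex), ("TEX", s_tex)):
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite {name} score")
    fam = "wt" if s_fam < th.fam_lo else ("het" if s_fam <= th.fam_hi else "hom")
    hex_ = "low" if s_hex < th.hex_lo else "high"
    tex = "low" if s_tex < th.tex_lo else "high"
    return fam, hex_, tex


def decision_table(levels: tuple[str, str, str]) -> str | None:
    """Map a level triple onto a genotype; None if no genotype matches."""
    fam, hex_, tex = levels
    if fam not in ("wt", "het", "hom") or hex_ not in ("low", "high") \
            or tex not in ("low", "high"):
        raise ValueError(f"invalid level triple {levels}")
    return DECISION_TABLE.get((fam, hex_, tex))


@dataclass
class GenotypeCall:
    """One sample's call with provenance."""

    sample_id: str
    call: str                       # genotype or 'INVALID'
    levels: tuple[str, str, str]
    scores: dict[str, float]
    qc_flag: str                    # 'pass' or a failure tag
    reason: str = ""

    def __post_init__(self) -> None:
        if self.call != "INVALID" and self.call not in GENOTYPES:
            raise ValueError(f"call must be a genotype or INVALID, got {self.call!r}")


def call_genotype(score, th: ThresholdSet | None = None) -> GenotypeCall:
    """Full calling logic for one sample.

    ``score`` is a :class:`casplex.scoring.GenotypeScore` or any object
    with ``sample_id`` and a ``scores`` dict over FAM/HEX/TEX.
    """
    th = th or ThresholdSet()
    scores = dict(score.scores)
    levels = classify_levels(scores, th)
    all_low = (scores["FAM"] < th.fam_lo and scores["HEX"] < th.hex_lo
               and scores["TEX"] < th.tex_lo)
    if all_low:
        return GenotypeCall(score.sample_id, "INVALID", levels, scores,
                            qc_flag="fail-all-low", reason="all-low/QC")
    geno = decision_table(levels)
    if geno is None:
        return GenotypeCall(score.sample_id, "INVALID", levels, scores,
                            qc_flag="fail-pattern", reason="no-genotype-combination")
    return GenotypeCall(score.sample_id, geno, levels, scores, qc_flag="pass")
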