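"""APOL1 allele bookkeeping shared across the pipeline.

The assay senses two kidney-disease risk variants of APOL1: G1 (the A>G
missense SNP rs73885319) and G2 (a 6-bp in-frame TTATAA deletion,
rs71785313); G0 denotes the wild-type allele. Two alleles give six
unordered genotypes. Three Cas enzymes report on them in three
fluorescence channels:

* FAM  — LwaCas13a, G1-mutant sensing: high with two G1 alleles,
  medium with one, low with none.
* HEX  — LbaCas12a, G2-mutant sensing: high with at least one G2 allele.
* TEX  — PsmCas13b, G2-wild-type sensing: high with at least one
  non-G2 allele (i.e. low only for G2G2).
"""

from __future__ import annotations

GENOTYPES: tuple[str, ...] = ("G0G0", "G0G1", "G1G1", "G0G2", "G1G2", "G2G2")
CHANNELS: tuple[str, ...] = ("FAM", "HEX", "TEX")

#: roles a well can play on a plate
ROLES: tuple[str, ...] = ("sample", "standard_sG1G1", "standard_sG2G2", "ntc")

#: which synthetic target-allele standard normalizes each channel
STANDARD_FOR_CHANNEL = {
    "FAM": "standard_sG1G1",   # LwaCas13a target allele
    "TEX": "standard_sG1G1",   # PsmCas13b target allele (G2 wt)
    "HEX": "standard_sG2G2",   # LbaCas12a target allele
}


def alleles(genotype: str) -> tuple[str, str]:
    """Split a genotype string into its two alleles, e.g. 'G1G2' -> ('G1','G2')."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return genotype[:2], genotype[2:]


def channel_levels(genotype: str) -> tuple[str, str, str]:
    """Expected qualitative signal level per channel for a genotype.

    Returns (fam_level, hex_level, tex_level) with fam in {low, med, high}
    and hex/tex in {low, high}, derived from allele content.
    """
    a, b = alleles(genotype)
    n_g1 = (a == "G1") + (b == "G1")
    any_g2 = "G2" in (a, b)
    any_non_g2 = a != "G2" or b != "G2"
    fam = ("low", "med", "high")[n_g1]
    hex_ = "high" if any_g2 else "low"
    tex = "high" if any_non_g2 else "low"
    return fam, hex_, tex


def assay_states(genotype: str) -> tuple[str, str]:
    """Lateral-flow assay states (g1_state, g2_state) for a genotype.

    Each two-stick assay reads wt / het / hom for its own variant from the
    count of that variant's alleles.
    """
    a, b = alleles(genotype)
    n_g1 = (a == "G1") + (b == "G1")
    n_g2 = (a == "G2") + (b == "G2")
    states = ("wt", "het", "hom")
    return states[n_g1], states[n_g2]
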