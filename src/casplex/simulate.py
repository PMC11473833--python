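"""Synthetic stand-ins for the assay's raw data.

Generates (a) per-well three-channel fluorescence kinetics with the level
structure the multiplexed Cas13/Cas12 assay produces (high / medium / low
per channel depending on allele content), (b) whole labeled cohorts with
technical replicates, target-allele standards, NTC wells and batch scale
effects, (c) grayscale two-band lateral-flow stick images, and (d)
nucleotide templates carrying the G1 SNP and the G2 TTATAA deletion.

Signal model for one well/channel (a saturating enzyme-progress curve):

    RFU(t) = b * (B + L * A * (1 - exp(-k t))) + eps_t,
    eps_t ~ Normal(0, sigma),  b ~ Lognormal(0, batch_scale_sd) per batch,

with L in {f_low, f_med, 1.0} the channel's level fraction for the well's
genotype (NTC wells sit at f_low). The multiplicative batch factor applies
equally to samples and standards of a batch, which is exactly what the
standard-normalized genotype score cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .alleles import CHANNELS, GENOTYPES, assay_states, channel_levels
from .io import KineticTrace, PlateSet

# ---------------------------------------------------------------------------
# kinetic signal model


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the saturating-exponential signal model.

    Defaults emulate a plate-reader run: baseline a few hundred RFU, a
    ~10^4 RFU dynamic range, a rate constant giving near-saturation within
    the hour, and per-read noise well under 1% of the dynamic range (the
    regime in which wild-type channels score below the 0.05 call
    threshold, as observed assay data do).
    """

    baseline: float = 200.0           # B, RFU
    amplitude_high: float = 10000.0   # A_hi, RFU
    amplitude_med_fraction: float = 0.5    # f_med
    amplitude_low_fraction: float = 0.02   # f_low
    rate: float = 0.1                 # k, 1/min
    noise_sd: float = 30.0            # sigma, RFU (moderate preset)
    batch_scale_sd: float = 0.15      # lognormal sd, log scale
    sampling_interval: float = 5.0    # min
    duration: float = 60.0            # min

    def __post_init__(self) -> None:
        if self.amplitude_high <= 0:
            raise ValueError("amplitude_high must be > 0")
        if not (0 < self.amplitude_low_fraction < self.amplitude_med_fraction < 1):
            raise ValueError("need 0 < f_low < f_med < 1")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.batch_scale_sd < 0:
            raise ValueError("batch_scale_sd must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration < 60:
            raise ValueError("duration must be >= 60 min")

    def with_noise_preset(self, preset: str) -> "SignalModelParams":
        """Return a copy with the named noise preset applied."""
        if preset not in NOISE_PRESETS:
            raise ValueError(f"unknown noise preset {preset!r}; expected {sorted(NOISE_PRESETS)}")
        return replace(self, noise_sd=NOISE_PRESETS[preset] * self.amplitude_high)

    @property
    def times(self) -> np.ndarray:
        n = int(math.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


#: per-read noise sd as a fraction of amplitude_high
NOISE_PRESETS = {"low": 0.001, "moderate": 0.003}

#: signal levels of the synthetic standards and NTC wells; the sG1G1
#: standard carries the target allele of LwaCas13a (FAM) and PsmCas13b
#: (TEX), the sG2G2 standard that of LbaCas12a (HEX).
ROLE_LEVELS = {
    "standard_sG1G1": channel_levels("G1G1"),
    "standard_sG2G2": channel_levels("G2G2"),
    "NTC": ("low", "low", "low"),
}


def _level_fraction(level: str, params: SignalModelParams) -> float:
    return {"low": params.amplitude_low_fraction,
            "med": params.amplitude_med_fraction,
            "high": 1.0}[level]


def signal_level(genotype_or_role: str, channel: str) -> str:
    """Qualitative level for a genotype or control role in a channel."""
    ch = channel.upper()
    if ch not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    key = genotype_or_role
    if key in GENOTYPES:
        levels = channel_levels(key)
    elif key in ROLE_LEVELS:
        levels = ROLE_LEVELS[key]
    elif key.lower() == "ntc":
        levels = ROLE_LEVELS["NTC"]
    else:
        raise ValueError(
            f"unknown genotype/role {genotype_or_role!r}; expected a genotype "
            f"{GENOTYPES} or a role in {tuple(ROLE_LEVELS)}")
    return levels[CHANNELS.index(ch)]


def generate_trace(genotype_or_role: str, channel: str,
                   params: SignalModelParams | None = None,
                   seed: int | None = None, *,
                   rng: np.random.Generator | None = None,
                   batch_scale: float = 1.0,
                   well: str = "A1", sample_id: str | None = None,
                   role: str = "sample", batch: str = "batch0") -> KineticTrace:
    """Simulate one well's kinetic trace in one channel.

    Exactly one of ``seed`` / ``rng`` supplies the randomness; the batch
    scale factor is passed in (so a whole batch shares it) and defaults
    to 1.
    """
    params = params or SignalModelParams()
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an rng")
        rng = np.random.default_rng(seed)
    level = signal_level(genotype_or_role, channel)
    if genotype_or_role.lower() == "ntc":
        role = "ntc"
    elif genotype_or_role in ROLE_LEVELS:
        role = genotype_or_role
    t = params.times
    frac = _level_fraction(level, params)
    mean = batch_scale * (params.baseline
                          + frac * params.amplitude_high * (1.0 - np.exp(-params.rate * t)))
    noise = rng.normal(0.0, params.noise_sd, size=t.size) if params.noise_sd > 0 else 0.0
    return KineticTrace(well=well, sample_id=sample_id or genotype_or_role, role=role,
                        batch=batch, channel=channel.upper(), times=t, rfus=mean + noise)


@dataclass
class Cohort:
    """A labeled synthetic cohort: the plate plus the truth labels."""

    plate: PlateSet
    truth: dict[str, str]   # sample_id -> genotype


def generate_cohort(n_per_genotype: int,
                    params: SignalModelParams | None = None,
                    replicate_count: int = 6,
                    include_standards: bool = True,
                    n_batches: int = 1,
                    ntc_count: int | None = None,
                    seed: int = 0) -> Cohort:
    """Simulate a full six-genotype cohort.

    Each sample gets ``replicate_count`` replicate traces per channel
    (mirroring six technical replicates per sample); each batch gets its
    own lognormal scale factor plus sG1G1/sG2G2 standard wells and NTC
    wells (``ntc_count`` defaults to ``replicate_count``). Samples are
    assigned to batches round-robin.
    """
    if n_per_genotype < 1:
        raise ValueError("n_per_genotype must be >= 1")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    params = params or SignalModelParams()
    ntc_count = replicate_count if ntc_count is None else ntc_count
    rng = np.random.default_rng(seed)
    batch_scales = {
        f"batch{b}": float(np.exp(rng.normal(0.0, params.batch_scale_sd)))
        if params.batch_scale_sd > 0 else 1.0
        for b in range(n_batches)
    }

    traces: list[KineticTrace] = []
    truth: dict[str, str] = {}
    well_no = 0

    def emit(label: str, role: str, sample_id: str, batch: str) -> None:
        nonlocal well_no
        n_rep = ntc_count if role == "ntc" else replicate_count
        for rep in range(n_rep):
            well_no += 1
            well = f"{batch}:W{well_no:04d}"
            for ch in CHANNELS:
                traces.append(generate_trace(
                    label, ch, params, rng=rng, batch_scale=batch_scales[batch],
                    well=well, sample_id=sample_id, role=role, batch=batch))

    idx = 0
    for geno in GENOTYPES:
        for i in range(n_per_genotype):
            batch = f"batch{idx % n_batches}"
            sid = f"{geno}_s{i:04d}"
            truth[sid] = geno
            emit(geno, "sample", sid, batch)
            idx += 1
    for batch in batch_scales:
        if include_standards:
            emit("standard_sG1G1", "standard_sG1G1", f"sG1G1_{batch}", batch)
            emit("standard_sG2G2", "standard_sG2G2", f"sG2G2_{batch}", batch)
        emit("NTC", "ntc", f"NTC_{batch}", batch)
    return Cohort(plate=PlateSet(traces), truth=truth)


# ---------------------------------------------------------------------------
# lateral-flow stick images

#: default stick geometry (rows, cols); see casplex.lfa.StickLayout
DEFAULT_IMAGE_SHAPE = (160, 60)

#: raw gray levels of the synthetic sticks (pre-normalization, ~8-bit scale)
STICK_GRAYS = {"blank": 205.0, "dark": 60.0, "faint": 195.0}

#: the six valid (g1_state, g2_state) pairs
VALID_STATE_PAIRS = {assay_states(g): g for g in GENOTYPES}


def default_layout(assay: str):
    """Band/blank rectangles of the synthetic sticks (0-based half-open)."""
    from .lfa import Rect, StickLayout
    return StickLayout(
        assay=assay,
        control=Rect(20, 32, 5, 55),
        streptavidin=Rect(60, 72, 5, 55),
        anti_digoxigenin=Rect(100, 112, 5, 55),
        blank=Rect(130, 155, 5, 55),
    )


def _paint_stick(assay: str, state: str, rng: np.random.Generator,
                 noise_sd: float):
    """One stick image; band absence (faint) signals target detection."""
    from .lfa import StickImage

    layout = default_layout(assay)
    img = np.full(DEFAULT_IMAGE_SHAPE, STICK_GRAYS["blank"], dtype=float)

    wt_detected = state in ("wt", "het")
    mut_detected = state in ("het", "hom")
    # band identity per assay: in the G1 assay the mutant sensor is
    # LwaCas13a (biotin reporter -> streptavidin band); in the G2 assay it
    # is LbaCas12a (digoxigenin reporter -> anti-digoxigenin band).
    if assay == "G1":
        mut_rect, wt_rect = layout.streptavidin, layout.anti_digoxigenin
    else:
        mut_rect, wt_rect = layout.anti_digoxigenin, layout.streptavidin

    def fill(rect, gray):
        img[rect.row0:rect.row1, rect.col0:rect.col1] = gray

    fill(layout.control, STICK_GRAYS["dark"])
    fill(mut_rect, STICK_GRAYS["faint"] if mut_detected else STICK_GRAYS["dark"])
    fill(wt_rect, STICK_GRAYS["faint"] if wt_detected else STICK_GRAYS["dark"])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return StickImage(image=np.clip(img, 0.0, None), layout=layout)


def generate_stick_image(g1_assay_state: str, g2_assay_state: str,
                         seed: int = 0, noise_sd: float = 3.0):
    """Synthetic two-stick readout for one sample.

    States must form one of the six pairs consistent with a valid
    genotype. Returns (g1_stick, g2_stick) as StickImage objects (float
    grayscale arrays plus their layouts).
    """
    pair = (g1_assay_state, g2_assay_state)
    if pair not in VALID_STATE_PAIRS:
        raise ValueError(
            f"state pair {pair} is inconsistent with any valid genotype; "
            f"valid pairs: {sorted(VALID_STATE_PAIRS)}")
    rng = np.random.default_rng(seed)
    g1 = _paint_stick("G1", g1_assay_state, rng, noise_sd)
    g2 = _paint_stick("G2", g2_assay_state, rng, noise_sd)
    return g1, g2


# ---------------------------------------------------------------------------
# nucleotide templates

#: spacing between the G1 SNP and the start of the G2 hexamer: codons
#: 342 -> 388, i.e. 46 codons * 3 nt
G1_G2_SPACING = 138

G2_HEXAMER = "TTATAA"


@dataclass(frozen=True)
class SyntheticTemplate:
    """A wild-type template plus the coordinates of both variants."""

    wt: str
    g1_pos: int                      # 0-based index of the A>G SNP
    g2_interval: tuple[int, int]     # 0-based half-open TTATAA interval
    context_len: int

    @property
    def alleles(self) -> dict[str, str]:
        """The four allele sequences: wt, G1, G2 and the G1+G2 haplotype."""
        wt = self.wt
        i = self.g1_pos
        a, b = self.g2_interval
        g1 = wt[:i] + "G" + wt[i + 1:]
        g2 = wt[:a] + wt[b:]
        g1g2 = g1[:a] + g1[b:]
        return {"wt": wt, "G1": g1, "G2": g2, "G1G2": g1g2}


def generate_templates(context_len: int = 300, seed: int = 0) -> SyntheticTemplate:
    """Random template (GC ~= 0.5) with the G1 SNP and G2 deletion planted.

    ``context_len`` is the flank on each side of the variant region and
    must be >= 300 so that 234-bp amplicons spanning both variants fit.
    """
    if context_len < 300:
        raise ValueError("context_len must be >= 300 to admit amplicons spanning both variants")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    g1_pos = context_len
    mid = rand(G1_G2_SPACING - 1)           # between the SNP and the hexamer
    right = rand(context_len)
    # the 6 nt after the hexamer must not themselves read TTATAA, so the
    # deletion allele verifiably lacks the hexamer at the recorded interval
    while right.startswith(G2_HEXAMER):
        right = rand(6) + right[6:]
    wt = rand(context_len) + "A" + mid + G2_HEXAMER + right
    g2_start = g1_pos + G1_G2_SPACING
    tmpl = SyntheticTemplate(wt=wt, g1_pos=g1_pos,
                             g2_interval=(g2_start, g2_start + 6),
                             context_len=context_len)
    assert tmpl.wt[g2_start:g2_start + 6] == G2_HEXAMER
    return tmpl


def write_templates_fasta(template: SyntheticTemplate, path: str | Path) -> None:
    """Write the four allele records as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(seq), id=name, description=f"synthetic APOL1 template allele {name}")
            for name, seq in template.alleles.items()]
    SeqIO.write(recs, str(path), "fasta")
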