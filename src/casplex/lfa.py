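"""Lateral-flow stick densitometry and two-stick genotype calls.

Quantification mirrors standard ImageJ practice: scale the image linearly
so the stick's blank region has mean gray 210, convert to 8-bit, invert
(so darker bands score higher), measure each band rectangle's mean gray,
and divide the test bands by the control band. Because target detection
CLEAVES the reporter, band absence (a low band/control ratio) signals
positive detection. Relative intensities are thresholded at 0.4 for the
LwaCas13a reporter band and 0.5 for the LbaCas12a reporter band;
combining the G1-assay and G2-assay states gives six unique band
patterns, one per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alleles import GENOTYPES, assay_states
from .genotyping import GenotypeCall

BLANK_TARGET_GRAY = 210.0

MIN_RECT_AREA = 25


@dataclass(frozen=True)
class Rect:
    """Pixel rectangle, 0-based half-open: rows [row0,row1), cols [col0,col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"degenerate rectangle {self}")
        if self.area < MIN_RECT_AREA:
            raise ValueError(f"rectangle area {self.area} < {MIN_RECT_AREA} px")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def overlaps(self, other: "Rect") -> bool:
        return not (self.row1 <= other.row0 or other.row1 <= self.row0
                    or self.col1 <= other.col0 or other.col1 <= self.col0)

    def slice(self, image: np.ndarray) -> np.ndarray:
        if self.row1 > image.shape[0] or self.col1 > image.shape[1]:
            raise ValueError(f"rectangle {self} exceeds image shape {image.shape}")
        return image[self.row0:self.row1, self.col0:self.col1]


@dataclass(frozen=True)
class StickLayout:
    """Band-region layout of one stick plus its assay tag (G1 or G2)."""

    assay: str
    blank: Rect
    control: Rect
    streptavidin: Rect
    anti_digoxigenin: Rect

    def __post_init__(self) -> None:
        if self.assay not in ("G1", "G2"):
            raise ValueError("assay must be 'G1' or 'G2'")
        rects = [self.blank, self.control, self.streptavidin, self.anti_digoxigenin]
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping rectangles {a} / {b}")

    @property
    def mutant_band(self) -> str:
        """Physical band carrying the mutant-sensing reporter for this assay."""
        return "streptavidin" if self.assay == "G1" else "anti_digoxigenin"

    @property
    def wt_band(self) -> str:
        return "anti_digoxigenin" if self.assay == "G1" else "streptavidin"


@dataclass
class StickImage:
    """A grayscale stick image (float array) with its layout."""

    image: np.ndarray
    layout: StickLayout


@dataclass(frozen=True)
class LFAThresholds:
    """Relative-band-intensity cutoffs, keyed by reporter enzyme."""

    lwa: float = 0.4   # LwaCas13a reporter band
    lba: float = 0.5   # LbaCas12a reporter band


@dataclass
class BandReadout:
    """Quantified stick: band means on the inverted 8-bit scale and ratios."""

    assay: str
    scale: float                      # brightness normalization factor
    mean_gray: dict[str, float]       # band name -> inverted 8-bit mean
    r_mut: float                      # mutant-sensing band / control
    r_wt: float                       # wt-sensing band / control


# ---------------------------------------------------------------------------
# quantification


def normalize_brightness(image: np.ndarray, blank_rect: Rect,
                         target: float = BLANK_TARGET_GRAY):
    """Scale the image so the blank region's mean gray equals ``target``.

    Returns (normalized image clipped to [0, 255], scale factor). The
    linear scale makes downstream band/control ratios invariant to global
    exposure changes.
    """
    img = np.asarray(image, dtype=float)
    blank_mean = float(blank_rect.slice(img).mean())
    if blank_mean <= 1e-6:
        raise ValueError(f"blank region mean gray {blank_mean:.3g} is zero or near-zero")
    scale = target / blank_mean
    return np.clip(img * scale, 0.0, 255.0), scale


def quantify(image: np.ndarray, layout: StickLayout, *,
             normalize: bool = True) -> BandReadout:
    """Measure band intensities and relative ratios on one stick.

    With ``normalize=True`` the blank-region brightness adjustment is
    applied first; the image is then converted to 8-bit, inverted, and
    each band rectangle's mean gray measured. Ratios divide the
    mutant-/wt-sensing test bands by the control band according to the
    layout's assay tag.
    """
    img = np.asarray(image, dtype=float)
    scale = 1.0
    if normalize:
        img, scale = normalize_brightness(img, layout.blank)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    inv = 255 - img8
    mean_gray = {name: float(getattr(layout, name).slice(inv).mean())
                 for name in ("blank", "control", "streptavidin", "anti_digoxigenin")}
    control = mean_gray["control"]
    if control <= 0:
        raise ValueError("control band mean gray is zero; stick unreadable")
    return BandReadout(
        assay=layout.assay, scale=scale, mean_gray=mean_gray,
        r_mut=mean_gray[layout.mutant_band] / control,
        r_wt=mean_gray[layout.wt_band] / control,
    )


def _band_threshold(assay: str, band_role: str, th: LFAThresholds) -> float:
    # G1 assay: mutant sensor LwaCas13a, wt sensor LbaCas12a; G2 assay the
    # reverse. Thresholds follow the reporter enzyme, not the band line.
    lwa_is_mut = assay == "G1"
    if band_role == "mut":
        return th.lwa if lwa_is_mut else th.lba
    return th.lba if lwa_is_mut else th.lwa


def call_assay_state(readout: BandReadout,
                     thresholds: LFAThresholds | None = None) -> str:
    """Band ratios -> assay state in {wt, het, hom, invalid}.

    A target counts as detected when its band's relative intensity falls
    below threshold (the band is absent because the reporter was cleaved).
    Mutant-only -> hom; both -> het; wt-only -> wt; neither -> invalid.
    """
    th = thresholds or LFAThresholds()
    mut_detected = readout.r_mut < _band_threshold(readout.assay, "mut", th)
    wt_detected = readout.r_wt < _band_threshold(readout.assay, "wt", th)
    if mut_detected and wt_detected:
        return "het"
    if mut_detected:
        return "hom"
    if wt_detected:
        return "wt"
    return "invalid"


#: (g1_state, g2_state) -> genotype; the six allele-consistent patterns
COMBINATION_TABLE: dict[tuple[str, str], str] = {
    ("wt", "wt"): "G0G0",
    ("het", "wt"): "G0G1",
    ("hom", "wt"): "G1G1",
    ("wt", "het"): "G0G2",
    ("het", "het"): "G1G2",
    ("wt", "hom"): "G2G2",
}


def combine_assays(g1_state: str, g2_state: str,
                   sample_id: str = "") -> GenotypeCall:
    """Combine the two assay states into a genotype call.

    Pairs not matching any genotype (e.g. hom/het, which would need more
    than two alleles, or anything involving an invalid stick) come back
    INVALID.
    """
    geno = COMBINATION_TABLE.get((g1_state, g2_state))
    levels = ("-", "-", "-")
    if geno is None:
        return GenotypeCall(sample_id, "INVALID", levels, {},
                            qc_flag="fail-pattern",
                            reason=f"band pattern ({g1_state},{g2_state}) matches no genotype")
    return GenotypeCall(sample_id, geno, levels, {}, qc_flag="pass")


def call_sticks(g1_stick: StickImage, g2_stick: StickImage,
                thresholds: LFAThresholds | None = None,
                sample_id: str = "") -> tuple[GenotypeCall, BandReadout, BandReadout]:
    """Quantify a two-stick pair end-to-end and call the genotype."""
    r1 = quantify(g1_stick.image, g1_stick.layout)
    r2 = quantify(g2_stick.image, g2_stick.layout)
    call = combine_assays(call_assay_state(r1, thresholds),
                          call_assay_state(r2, thresholds), sample_id)
    return call, r1, r2


# ---------------------------------------------------------------------------
# file I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as a float array (original bit scale)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image")
    return arr.astype(float)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float grayscale image as 16-bit PNG/TIFF (values 0-255 scaled)."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 255.0)
    iio.imwrite(path, (arr * 257.0).round().astype(np.uint16))


def load_layout(path: str | Path) -> StickLayout:
    """Load a layout from YAML: assay tag plus [row0,row1,col0,col1] rectangles."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rects = {k: Rect(*data[k]) for k in ("blank", "control", "streptavidin",
                                         "anti_digoxigenin")}
    return StickLayout(assay=data["assay"], **rects)


def save_layout(layout: StickLayout, path: str | Path) -> None:
    import yaml

    data = {"assay": layout.assay}
    for k in ("blank", "control", "streptavidin", "anti_digoxigenin"):
        r = getattr(layout, k)
        data[k] = [r.row0, r.row1, r.col0, r.col1]
    Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")
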