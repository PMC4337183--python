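"""Simulated 2DE gel cohorts with planted differential truth.

Two groups of gels (a comparison group such as P7 or P637, and the P90
reference group) are generated from a protein catalog.  A subset of
proteins is planted as up-regulated, down-regulated, or absent in one
group; every spot volume is the group's true mean volume multiplied by
lognormal noise, each spot can drop out per gel, and each gel carries a
small random affine distortion of the coordinate grid, so the downstream
detection → matching → normalization → SVQ chain is exercised under
realistic (but fully known) conditions.

Coordinate conventions (stated once, applied everywhere): continuous
coordinates with origin top-left; x runs acidic→basic (pH 3 at x=0) with
a piecewise-linear map that compresses the basic 7–10 segment, emulating
a nonlinear pH 3–10 strip; y is linear in log10(MW) with 100 kDa at the
top and 10 kDa at the bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ProteinRecord
from .diffexp import DEFAULT_HIGH, DEFAULT_LOW
from .gel_analysis import GelSpotTable

__all__ = [
    "EffectDesign", "CohortTruth", "TruthSpot", "InvalidDesignError",
    "plant_effects", "generate_cohort", "render_gel",
    "pi_to_x", "mw_to_y", "random_gel", "sample_spot_counts",
    "p7_design", "p637_design", "SPOT_COUNT_STATS", "GEL_WIDTH", "GEL_HEIGHT",
]

GEL_WIDTH = 1000.0
GEL_HEIGHT = 1000.0

#: per-group detected-spot count (mean, SD) across six gels
SPOT_COUNT_STATS = {"P7": (828.0, 71.0), "P90": (775.0, 152.0),
                    "P637": (785.0, 56.0)}

# planted classes
UP, DOWN, ABSENT_CMP, ABSENT_P90, UNCHANGED = (
    "up", "down", "absent_cmp", "absent_p90", "unchanged")


class InvalidDesignError(ValueError):
    """Effect design violates its constraints."""


@dataclass
class EffectDesign:
    """Composition and noise model of one two-group comparison.

    ``effect_size`` is the true SVQ magnitude (P90 mean ÷ comparison
    mean for "down" proteins, its reciprocal for "up"); it must lie
    strictly above the upper calling threshold so planted effects are
    callable.  ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal volume noise; ``dropout`` the per-gel
    probability that a true spot goes undetected.
    """

    comparison: str = "P7-vs-P90"
    n_up: int = 0
    n_down: int = 0
    n_absent_cmp: int = 0
    n_absent_p90: int = 0
    n_unchanged: int | None = None
    effect_size: float = 2.5
    noise_cv: float = 0.10
    dropout: float = 0.05
    gels_per_group: int = 6
    seed: int = 0

    @property
    def cmp_label(self) -> str:
        return self.comparison.split("-vs-")[0]

    @property
    def ref_label(self) -> str:
        parts = self.comparison.split("-vs-")
        return parts[1] if len(parts) > 1 else "P90"

    def validate(self) -> None:
        counts = (self.n_up, self.n_down, self.n_absent_cmp,
                  self.n_absent_p90)
        if any(c < 0 for c in counts):
            raise InvalidDesignError("planted counts must be >= 0")
        if not self.effect_size > DEFAULT_HIGH:
            raise InvalidDesignError(
                f"effect_size {self.effect_size} lies inside the null band "
                f"[{DEFAULT_LOW}, {DEFAULT_HIGH}]; planted effects would not "
                "be callable")
        if not (0 <= self.dropout < 0.5):
            raise InvalidDesignError("dropout must be in [0, 0.5)")
        if self.noise_cv < 0:
            raise InvalidDesignError("noise_cv must be >= 0")
        if self.gels_per_group < 1:
            raise InvalidDesignError("gels_per_group must be >= 1")


def p7_design(seed: int = 0, **overrides) -> EffectDesign:
    """Default P7-vs-P90 design: planted composition 63/51/9/6 (total 129)."""
    kw = dict(comparison="P7-vs-P90", n_up=63, n_down=51,
              n_absent_cmp=9, n_absent_p90=6, seed=seed)
    kw.update(overrides)
    return EffectDesign(**kw)


def p637_design(seed: int = 0, **overrides) -> EffectDesign:
    """Default P637-vs-P90 design: planted composition 25/14/4/4 (total 47)."""
    kw = dict(comparison="P637-vs-P90", n_up=25, n_down=14,
              n_absent_cmp=4, n_absent_p90=4, seed=seed)
    kw.update(overrides)
    return EffectDesign(**kw)


@dataclass(frozen=True)
class TruthSpot:
    """One physical spot of a protein: gel position and volume share."""

    accession: str
    spot_index: int
    pi: float
    mw: float
    fraction: float     # share of the protein's volume carried by this spot


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``group_means`` maps accession → (comparison-group mean, P90 mean)
    in arbitrary volume units; an absent class has exactly 0 in one
    group.  ``classes`` maps accession → planted class label.
    """

    proteins: list[ProteinRecord]
    classes: dict[str, str]
    group_means: dict[str, tuple[float, float]]
    spots: list[TruthSpot]
    gels_per_group: int
    comparison: str
    spot_positions: pd.DataFrame = field(init=False)

    def __post_init__(self):
        pis = np.array([s.pi for s in self.spots], dtype=float)
        mws = np.array([s.mw for s in self.spots], dtype=float)
        self.spot_positions = pd.DataFrame({
            "spot_id": [f"{s.accession}.{s.spot_index}" for s in self.spots],
            "accession": [s.accession for s in self.spots],
            "x": np.asarray(pi_to_x(pis), dtype=float),
            "y": np.asarray(mw_to_y(mws), dtype=float),
        })

    def true_svq(self, accession: str) -> float:
        """True SVQ (P90 mean ÷ comparison mean); NaN when a mean is 0."""
        cmp_mean, ref_mean = self.group_means[accession]
        if cmp_mean == 0 or ref_mean == 0:
            return float("nan")
        return ref_mean / cmp_mean


def pi_to_x(pi, width: float = GEL_WIDTH, basic_fraction: float = 0.3):
    """Map pI to the x axis: piecewise-linear nonlinear pH 3–10 gradient.

    pH 3–7 spans the left ``1 - basic_fraction`` of the gel, pH 7–10 is
    compressed into the right ``basic_fraction``.
    """
    pi = np.asarray(pi, dtype=float)
    split = (1.0 - basic_fraction) * width
    acid = (pi - 3.0) / 4.0 * split
    base = split + (pi - 7.0) / 3.0 * (width - split)
    return np.where(pi <= 7.0, acid, base)


def mw_to_y(mw, height: float = GEL_HEIGHT):
    """Map MW to the y axis: linear in log10(MW), 100 kDa top, 10 kDa bottom."""
    mw = np.asarray(mw, dtype=float)
    return (5.0 - np.log10(mw)) * height


def plant_effects(catalog: list[ProteinRecord],
                  design: EffectDesign) -> CohortTruth:
    """Assign planted classes and true group-mean volumes to a catalog.

    Selected proteins get true SVQ = ``effect_size`` (down at the
    comparison stage), ``1/effect_size`` (up), or a zero mean in exactly
    one group (absent); all remaining proteins are unchanged (true
    SVQ = 1).  Baseline abundances are lognormal.  A protein's volume is
    split across its ``n_spots`` isoform spots by a Dirichlet draw, with
    small pI offsets between the isoforms.
    """
    design.validate()
    n_planted = (design.n_up + design.n_down + design.n_absent_cmp
                 + design.n_absent_p90)
    if n_planted > len(catalog):
        raise InvalidDesignError(
            f"{n_planted} planted proteins exceed catalog size {len(catalog)}")
    if design.n_unchanged is not None and \
            n_planted + design.n_unchanged != len(catalog):
        raise InvalidDesignError(
            "n_unchanged must equal catalog size minus planted counts")

    rng = np.random.default_rng([design.seed, 0])
    order = rng.permutation(len(catalog))
    labels = ([UP] * design.n_up + [DOWN] * design.n_down
              + [ABSENT_CMP] * design.n_absent_cmp
              + [ABSENT_P90] * design.n_absent_p90)
    labels += [UNCHANGED] * (len(catalog) - len(labels))

    classes, means, spots = {}, {}, []
    for idx, label in zip(order, labels):
        rec = catalog[idx]
        baseline = float(rng.lognormal(np.log(100.0), 0.8))
        if label == UP:          # higher at the comparison stage
            cmp_mean, ref_mean = baseline * design.effect_size, baseline
        elif label == DOWN:
            cmp_mean, ref_mean = baseline / design.effect_size, baseline
        elif label == ABSENT_CMP:
            cmp_mean, ref_mean = 0.0, baseline
        elif label == ABSENT_P90:
            cmp_mean, ref_mean = baseline, 0.0
        else:
            cmp_mean, ref_mean = baseline, baseline
        classes[rec.accession] = label
        means[rec.accession] = (cmp_mean, ref_mean)
        if rec.n_spots == 1:
            fracs = np.array([1.0])
        else:
            fracs = rng.dirichlet(np.full(rec.n_spots, 5.0))
        ladder = (np.arange(rec.n_spots) - (rec.n_spots - 1) / 2) * 0.15
        for k in range(rec.n_spots):
            pi_k = float(np.clip(rec.pi + ladder[k]
                                 + rng.normal(0, 0.02), 3.0, 10.0))
            spots.append(TruthSpot(rec.accession, k, pi_k, rec.mw,
                                   float(fracs[k])))
    return CohortTruth(proteins=list(catalog), classes=classes,
                       group_means=means, spots=spots,
                       gels_per_group=design.gels_per_group,
                       comparison=design.comparison)


def generate_cohort(
    truth: CohortTruth,
    design: EffectDesign,
    *,
    position_jitter: float = 0.5,
    affine_jitter: bool = True,
) -> tuple[list[GelSpotTable], list[GelSpotTable]]:
    """Simulate the two gel groups: (comparison gels, P90 gels).

    Per gel and spot: volume = true group mean × spot fraction ×
    lognormal noise with CV ``design.noise_cv`` (unit mean); the spot is
    dropped with probability ``design.dropout``; positions receive a
    small per-gel affine distortion (rotation/scale/translation about the
    gel centre) plus isotropic jitter of ``position_jitter`` units.
    Pure function of (truth, design): identical seeds give identical
    tables.  Synthetic spot_ids encode the truth (``accession.k``).
    """
    design.validate()
    rng = np.random.default_rng([design.seed, 1])
    sigma = float(np.sqrt(np.log1p(design.noise_cv ** 2)))
    pos = truth.spot_positions
    base_xy = pos[["x", "y"]].to_numpy(dtype=float)
    spot_ids = pos["spot_id"].to_numpy()
    cmp_means = np.array([truth.group_means[a][0] for a in pos["accession"]])
    ref_means = np.array([truth.group_means[a][1] for a in pos["accession"]])
    fracs = np.array([s.fraction for s in truth.spots])

    def make_gel(gel_id: str, group_means: np.ndarray) -> GelSpotTable:
        if affine_jitter:
            theta = rng.normal(0, 0.003)
            scale = rng.normal(1.0, 0.002)
            shift = rng.normal(0, 2.0, size=2)
        else:
            theta, scale, shift = 0.0, 1.0, np.zeros(2)
        centre = np.array([GEL_WIDTH / 2, GEL_HEIGHT / 2])
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = (base_xy - centre) @ (scale * rot).T + centre + shift
        xy = xy + rng.normal(0, position_jitter, size=xy.shape)
        noise = (np.exp(rng.normal(-sigma ** 2 / 2, sigma, len(base_xy)))
                 if sigma > 0 else np.ones(len(base_xy)))
        volumes = group_means * fracs * noise
        keep = (volumes > 0) & (rng.random(len(base_xy)) >= design.dropout)
        return GelSpotTable(gel_id=gel_id, spots=pd.DataFrame({
            "spot_id": spot_ids[keep],
            "x": xy[keep, 0], "y": xy[keep, 1],
            "volume": volumes[keep],
        }))

    n = design.gels_per_group
    cmp_gels = [make_gel(f"{design.cmp_label}_{i+1:02d}", cmp_means)
                for i in range(n)]
    ref_gels = [make_gel(f"{design.ref_label}_{i+1:02d}", ref_means)
                for i in range(n)]
    return cmp_gels, ref_gels


def render_gel(
    gel: GelSpotTable,
    width: int = 1000,
    height: int = 1000,
    *,
    spot_sigma: float = 2.0,
    gain: float = 20.0,
    background: float = 100.0,
    read_noise: float = 2.0,
    bit_depth: int = 12,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a spot table as a 16-bit grayscale gel image.

    Each spot is an isotropic 2-D Gaussian of width ``spot_sigma`` whose
    integrated intensity equals ``gain × volume``; a constant background
    offset and Gaussian read noise emulate scanner response, and
    intensities are clipped to the 12-bit range of a flatbed gel scan
    (stored in a uint16 container).  Spots outside the image raise a
    warning and are skipped.  ``read_noise=0`` gives a noiseless render.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    img = np.zeros((height, width), dtype=float)
    half = int(np.ceil(5 * spot_sigma))
    amp_norm = 2 * np.pi * spot_sigma ** 2
    for _, row in gel.spots.iterrows():
        x, y, vol = float(row["x"]), float(row["y"]), float(row["volume"])
        if not (0 <= x < width and 0 <= y < height):
            warnings.warn(
                f"spot {row['spot_id']} at ({x:.1f}, {y:.1f}) outside the "
                f"{width}x{height} window; skipped", stacklevel=2)
            continue
        x0, x1 = max(0, int(x) - half), min(width, int(x) + half + 1)
        y0, y1 = max(0, int(y) - half), min(height, int(y) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += (gain * vol / amp_norm) * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * spot_sigma ** 2))
    img += background
    if read_noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img += rng.normal(0, read_noise, img.shape)
    np.clip(img, 0, 2 ** bit_depth - 1, out=img)
    return np.round(img).astype(np.uint16)


def sample_spot_counts(mean: float, sd: float, n_gels: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-gel true spot counts drawn from a normal(mean, sd), rounded."""
    return np.maximum(1, np.round(rng.normal(mean, sd, n_gels))).astype(int)


def random_gel(gel_id: str, n_spots: int, rng: np.random.Generator,
               min_separation: float = 0.0) -> GelSpotTable:
    """A gel of ``n_spots`` spots at random separable positions.

    Positions are uniform in pI 3.1–9.9 and log-uniform in MW 10.5–95 kDa
    (mapped through the standard axes); volumes are lognormal around 100.
    Used for detector-calibration cohorts where only counts matter.
    With ``min_separation`` > 0 positions are rejection-sampled so no two
    spots lie closer than that (a resolvable-spot fixture: co-migrating
    spots physically merge on a gel and no detector can split them).
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")

    def draw(k):
        pi = rng.uniform(3.1, 9.9, k)
        mw = 10 ** rng.uniform(np.log10(10_500), np.log10(95_000), k)
        return np.column_stack([pi_to_x(pi), mw_to_y(mw)])

    xy = draw(n_spots)
    if min_separation > 0:
        from scipy.spatial import cKDTree
        for _ in range(200):
            pairs = cKDTree(xy).query_pairs(min_separation)
            if not pairs:
                break
            redo = sorted({j for _, j in pairs})
            xy[redo] = draw(len(redo))
        else:
            raise RuntimeError("could not satisfy min_separation")
    return GelSpotTable(gel_id=gel_id, spots=pd.DataFrame({
        "spot_id": [f"{gel_id}.t{i:04d}" for i in range(n_spots)],
        "x": xy[:, 0], "y": xy[:, 1],
        "volume": rng.lognormal(np.log(100.0), 0.8, n_spots),
    }))
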