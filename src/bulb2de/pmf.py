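"""Peptide-mass-fingerprint (PMF) identification of gel spots.

A protein excised from a gel is digested with trypsin and its MALDI-TOF
peptide masses are matched against the in-silico digest of every database
entry.  Matching uses a ppm tolerance (default 60 ppm) after removing
known contaminant masses (trypsin autolysis products, CHCA matrix
clusters).  The identification score is probability-based in the Mascot
tradition: score = −10·log10 P, where P is the binomial upper-tail
probability of observing at least the matched number of peaks by chance.
An identification is significant at level α against a database of N
sequences when its score exceeds −10·log10(α/N), the Bonferroni-style
identity threshold (N = 42755 rat sequences and α = 0.05 give 59).

Fixed modification: carbamidomethyl-Cys (+57.021464 Da); variable:
Met oxidation (+15.994915 Da per site).  Masses are monoisotopic and
peaks singly protonated, as usual for reflector-mode MALDI-TOF PMF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy import stats

from .physchem import MONO_RESIDUE_MASS, PROTON, WATER_MONO, _validate

__all__ = [
    "PeptideMass", "PeptideMassList", "PMFIdentification", "PMFParams",
    "digest", "match_peaks", "score", "significance_threshold", "search",
    "default_exclusion_masses", "theoretical_peak_list",
    "synthetic_peak_list", "read_peak_list", "write_peak_list",
]

CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915

with resources.files("bulb2de.data").joinpath("exclusion_list.json").open() as _fh:
    _EXCL = json.load(_fh)


def default_exclusion_masses() -> np.ndarray:
    """Default contaminant [M+H]+ masses excluded before matching."""
    return np.array(sorted(_EXCL["trypsin_autolysis"]
                           + _EXCL["matrix_clusters"]))


@dataclass(frozen=True)
class PeptideMass:
    sequence: str
    missed_cleavages: int
    n_oxidations: int
    mass: float            # neutral monoisotopic mass, Da

    @property
    def mz(self) -> float:
        """Singly-protonated [M+H]+ m/z."""
        return self.mass + PROTON


@dataclass
class PeptideMassList:
    """Theoretical peptides of one protein, with modification states."""

    accession: str
    peptides: list[PeptideMass]

    def mz_array(self) -> np.ndarray:
        return np.array(sorted(p.mz for p in self.peptides))


@dataclass(frozen=True)
class PMFIdentification:
    accession: str
    n_matched: int
    n_observed_peaks: int
    score: float
    significant: bool


@dataclass
class PMFParams:
    tol_ppm: float = 60.0
    max_missed: int = 1
    alpha: float = 0.05
    min_mass: float = 700.0
    max_mass: float = 4000.0
    #: peptide monoisotopic masses are not uniform on the mass axis: they
    #: cluster in mass-defect bands occupying roughly a quarter of each
    #: Dalton, so a peptide-like peak meets database peptide masses ~4x
    #: more often than a uniform-density model predicts.
    mass_defect_factor: float = 4.0


def _peptide_mass(sequence: str, n_ox: int) -> float:
    base = sum(MONO_RESIDUE_MASS[aa] for aa in sequence) + WATER_MONO
    return (base + CARBAMIDOMETHYL * sequence.count("C")
            + OXIDATION * n_ox)


def cleavage_sites(sequence: str) -> list[int]:
    """Tryptic cleavage positions: after K or R unless followed by P."""
    return [i + 1 for i, aa in enumerate(sequence[:-1])
            if aa in "KR" and sequence[i + 1] != "P"]


def digest(
    sequence: str,
    max_missed: int = 1,
    *,
    min_mass: float = 0.0,
    max_mass: float = float("inf"),
    accession: str = "",
) -> PeptideMassList:
    """In-silico tryptic digest with missed cleavages and modifications.

    Cleaves C-terminal to K/R except before P; emits every peptide with
    0..``max_missed`` internal missed sites, each expanded into all
    Met-oxidation count variants (Cys carbamidomethylation is fixed and
    always applied).  Peptides outside [min_mass, max_mass] (neutral Da)
    are dropped.
    """
    _validate(sequence)
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    peptides: list[PeptideMass] = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            pep = sequence[bounds[i]:bounds[j]]
            for n_ox in range(pep.count("M") + 1):
                m = _peptide_mass(pep, n_ox)
                if min_mass <= m <= max_mass:
                    peptides.append(PeptideMass(pep, missed, n_ox, m))
    return PeptideMassList(accession=accession, peptides=peptides)


def filter_excluded(observed, exclusion=None, tol_ppm: float = 60.0):
    """Drop observed peaks within tolerance of a contaminant mass."""
    observed = np.asarray(observed, dtype=float)
    excl = (default_exclusion_masses() if exclusion is None
            else np.asarray(exclusion, dtype=float))
    if len(excl) == 0 or len(observed) == 0:
        return observed
    keep = np.ones(len(observed), dtype=bool)
    for i, mz in enumerate(observed):
        if np.any(np.abs(excl - mz) / mz <= tol_ppm * 1e-6):
            keep[i] = False
    return observed[keep]


def match_peaks(
    observed,
    theoretical: PeptideMassList,
    tol_ppm: float = 60.0,
    exclusion=None,
) -> list[tuple[float, float]]:
    """Match observed m/z peaks to theoretical peptide masses.

    A peak matches when |Δm|/m ≤ tol_ppm·1e-6; each observed peak counts
    at most once, taking the nearest theoretical mass.  Contaminant peaks
    are removed before matching (pass ``exclusion=[]`` to disable).
    Returns (observed_mz, theoretical_mz) pairs.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    observed = filter_excluded(observed, exclusion, tol_ppm)
    theo = theoretical.mz_array()
    matches = []
    if len(theo) == 0:
        return matches
    for mz in observed:
        idx = np.searchsorted(theo, mz)
        best, err = None, np.inf
        for j in (idx - 1, idx):
            if 0 <= j < len(theo) and abs(theo[j] - mz) < err:
                best, err = theo[j], abs(theo[j] - mz)
        if best is not None and err / mz <= tol_ppm * 1e-6:
            matches.append((float(mz), float(best)))
    return matches


def score(n_matched: int, n_observed_peaks: int, p_single: float) -> float:
    """Probability-based identification score, −10·log10 P.

    P is the binomial upper tail P(X ≥ n_matched | n_observed_peaks,
    p_single), the chance of at least as many random matches; no matches
    give P = 1 and score 0.  Larger scores mean stronger evidence.
    """
    if not 0 <= n_matched <= n_observed_peaks:
        raise ValueError("need 0 <= n_matched <= n_observed_peaks")
    if not 0 < p_single < 1:
        raise ValueError(f"p_single must be in (0, 1), got {p_single}")
    if n_matched == 0:
        return 0.0
    p = float(stats.binom.sf(n_matched - 1, n_observed_peaks, p_single))
    return -10.0 * np.log10(max(p, 1e-300))


def significance_threshold(n_db_sequences: int,
                           alpha: float = 0.05) -> tuple[float, int]:
    """Score needed for significance at level ``alpha`` against N entries.

    The Bonferroni-style identity threshold −10·log10(alpha/N), returned
    as (real value, floored integer).  Strictly increasing in N and
    decreasing in alpha.
    """
    if n_db_sequences < 1:
        raise ValueError("n_db_sequences must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    value = -10.0 * np.log10(alpha / n_db_sequences)
    return float(value), int(np.floor(value))


def estimate_p_single(theoretical: PeptideMassList, observed,
                      params: PMFParams) -> float:
    """Per-peak random-match probability for one database entry.

    Density of the entry's theoretical peptide masses over the considered
    mass window, times the width of one matching window (2 × tol at the
    mean observed m/z), times the mass-defect clustering factor (peaks
    and peptide masses share the same sub-Dalton bands).
    """
    n_masses = len({round(p.mz, 4) for p in theoretical.peptides})
    span = params.max_mass - params.min_mass
    mean_mz = float(np.mean(observed)) if len(observed) else 1500.0
    width = 2.0 * params.tol_ppm * 1e-6 * mean_mz
    p = n_masses / span * width * params.mass_defect_factor
    return float(np.clip(p, 1e-9, 0.999))


def _iter_database(database):
    if isinstance(database, (str, Path)):
        for rec in SeqIO.parse(str(database), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for entry in database:
            if isinstance(entry, PeptideMassList):
                yield entry.accession, entry
            else:
                yield entry


def digest_database(database, params: PMFParams | None = None
                    ) -> list[PeptideMassList]:
    """Digest every database entry once, for repeated searches."""
    params = params or PMFParams()
    return [digest(seq, params.max_missed, min_mass=params.min_mass,
                   max_mass=params.max_mass, accession=acc)
            for acc, seq in _iter_database(database)]


def search(
    peaklist,
    database,
    params: PMFParams | None = None,
) -> list[PMFIdentification]:
    """PMF database search: digest, match and score every entry.

    ``database`` is a FASTA path or an iterable of (accession, sequence).
    Results are ranked by score descending (ties by accession) and the
    significance flag uses the database size N, so all proteins above the
    α-level threshold are reported (a sample can contain several).
    """
    params = params or PMFParams()
    entries = list(_iter_database(database))
    if not entries:
        raise ValueError("empty database")
    observed = filter_excluded(np.asarray(peaklist, dtype=float),
                               None, params.tol_ppm)
    if len(observed) == 0:
        warnings.warn("no peaks left after exclusion filtering",
                      stacklevel=2)
        return []
    _, thr = significance_threshold(len(entries), params.alpha)
    results = []
    for acc, seq in entries:
        if isinstance(seq, PeptideMassList):
            theo = seq
        else:
            theo = digest(seq, params.max_missed, min_mass=params.min_mass,
                          max_mass=params.max_mass, accession=acc)
        matches = match_peaks(observed, theo, params.tol_ppm, exclusion=[])
        p1 = estimate_p_single(theo, observed, params)
        s = score(len(matches), len(observed), p1)
        results.append(PMFIdentification(
            accession=acc, n_matched=len(matches),
            n_observed_peaks=len(observed), score=s,
            significant=s > thr))
    results.sort(key=lambda r: (-r.score, r.accession))
    return results


def theoretical_peak_list(sequence: str,
                          params: PMFParams | None = None) -> np.ndarray:
    """Sorted [M+H]+ m/z values of a protein's unmodified-Met digest."""
    params = params or PMFParams()
    theo = digest(sequence, params.max_missed, min_mass=params.min_mass,
                  max_mass=params.max_mass)
    return np.array(sorted({p.mz for p in theo.peptides
                            if p.n_oxidations == 0}))


def synthetic_peak_list(
    sequence: str,
    rng: np.random.Generator,
    n_peaks: tuple[int, int] = (8, 25),
    ppm_jitter: float = 30.0,
    contaminant_fraction: float = 0.2,
    params: PMFParams | None = None,
) -> np.ndarray:
    """Simulated MALDI peak list for a known protein (test fixture).

    Samples 8–25 of the protein's theoretical peptide m/z values, jitters
    each within ±``ppm_jitter``, and adds ~20% random contaminant peaks.
    Purely mass-level; no intensity or isotope simulation.
    """
    params = params or PMFParams()
    theo = theoretical_peak_list(sequence, params)
    if len(theo) == 0:
        raise ValueError("protein yields no peptides in the mass window")
    k = int(rng.integers(n_peaks[0], n_peaks[1] + 1))
    k = min(k, len(theo))
    picked = rng.choice(theo, size=k, replace=False)
    picked = picked * (1 + rng.uniform(-ppm_jitter, ppm_jitter, k) * 1e-6)
    n_cont = int(np.round(contaminant_fraction * k))
    cont = rng.uniform(params.min_mass, params.max_mass, n_cont) + PROTON
    return np.sort(np.concatenate([picked, cont]))


def read_peak_list(path) -> np.ndarray:
    """Read a peak list: two-column text (m/z, intensity) or MGF."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        from pyteomics import mgf
        with mgf.read(str(path)) as reader:
            spectrum = next(iter(reader))
        return np.sort(np.asarray(spectrum["m/z array"], dtype=float))
    data = np.loadtxt(path, ndmin=2)
    return np.sort(data[:, 0])


def write_peak_list(mz, path, intensities=None) -> None:
    """Write a two-column (m/z, intensity) text peak list."""
    mz = np.asarray(mz, dtype=float)
    inten = (np.ones_like(mz) if intensities is None
             else np.asarray(intensities, dtype=float))
    np.savetxt(path, np.column_stack([mz, inten]), fmt="%.6f\t%.2f")
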