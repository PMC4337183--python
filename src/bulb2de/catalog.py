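"""Synthetic protein catalogs for simulated 2DE cohorts.

A catalog is a list of :class:`ProteinRecord` — random but realistic
protein sequences whose derived pI and MW fall inside the separable window
of an immobilized pH 3–10 strip and a 12% SDS gel (~10–100 kDa).  Records
outside the window are rejected and resampled, mimicking the fact that a
2DE gel only ever shows the separable subproteome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import (
    AVG_RESIDUE_MASS,
    WATER_AVG,
    ionizable_counts,
    pi_from_counts,
)

__all__ = ["ProteinRecord", "CATEGORIES", "generate_catalog",
           "write_catalog", "read_catalog"]

#: the 13 functional classes used for category summaries:
#: carbohydrate/amino-acid/fat/energy metabolism, degradation, antioxidants,
#: transmitter metabolism, biosynthesis, signal transduction, regulation,
#: chaperones, structural and transport proteins.
CATEGORIES = ("pcm", "paam", "pfm", "pem", "pd", "pa", "ptm",
              "pb", "pst", "pr", "cp", "sp", "tp")

# SwissProt-like amino-acid background frequencies
_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}
_AA = np.array(list(_AA_FREQ))
_P = np.array(list(_AA_FREQ.values()))
_P = _P / _P.sum()
_RESIDUE_AVG = np.array([AVG_RESIDUE_MASS[aa] for aa in _AA])


@dataclass(frozen=True)
class ProteinRecord:
    """One catalog protein with derived gel coordinates and ground truth."""

    accession: str
    sequence: str
    pi: float
    mw: float          # average MW in Da (the gel axis)
    category: str
    n_spots: int = 1   # isoform/PTM spot multiplicity on the gel

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")


def generate_catalog(
    n: int,
    seed: int,
    *,
    pi_window: tuple[float, float] = (3.0, 10.0),
    mw_window: tuple[float, float] = (10_000.0, 100_000.0),
    multi_spot_fraction: float = 0.15,
) -> list[ProteinRecord]:
    """Generate ``n`` random proteins inside the separable pI/MW window.

    Sequences are drawn from SwissProt-like letter frequencies with
    lengths log-uniform in 90–880 residues (≈10–100 kDa); candidates whose
    derived pI or MW fall outside the window are rejected and resampled.
    By default 85% of proteins produce a single spot and 15% produce 2–3
    spots (charge/PTM isoforms), exercising multi-spot aggregation.
    Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError(f"catalog size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    while len(records) < n:
        length = int(np.exp(rng.uniform(np.log(90), np.log(880))))
        letters = rng.choice(_AA, size=length, p=_P)
        seq = "".join(letters)
        mw = float(sum(AVG_RESIDUE_MASS[aa] for aa in seq) + WATER_AVG)
        pi = float(pi_from_counts(ionizable_counts(seq))[0])
        if not (pi_window[0] <= pi <= pi_window[1]):
            continue
        if not (mw_window[0] <= mw <= mw_window[1]):
            continue
        u = rng.random()
        if u < 1 - multi_spot_fraction:
            n_spots = 1
        elif u < 1 - multi_spot_fraction / 3:
            n_spots = 2
        else:
            n_spots = 3
        records.append(ProteinRecord(
            accession=f"SYN{len(records):04d}",
            sequence=seq,
            pi=pi,
            mw=mw,
            category=str(rng.choice(CATEGORIES)),
            n_spots=n_spots,
        ))
    return records


def write_catalog(records: list[ProteinRecord], fasta_path, meta_path) -> None:
    """Write sequences as FASTA plus a sidecar CSV (accession, category, n_spots)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="")
            for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(meta_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession", "category", "n_spots"])
        for r in records:
            w.writerow([r.accession, r.category, r.n_spots])


def read_catalog(fasta_path, meta_path) -> list[ProteinRecord]:
    """Round-trip reader for :func:`write_catalog` output (recomputes pI/MW)."""
    meta = {}
    with open(meta_path, newline="") as fh:
        for row in csv.DictReader(fh):
            meta[row["accession"]] = (row["category"], int(row["n_spots"]))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        category, n_spots = meta[rec.id]
        records.append(ProteinRecord(
            accession=rec.id,
            sequence=seq,
            pi=float(pi_from_counts(ionizable_counts(seq))[0]),
            mw=float(sum(AVG_RESIDUE_MASS[aa] for aa in seq) + WATER_AVG),
            category=category,
            n_spots=n_spots,
        ))
    return records
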