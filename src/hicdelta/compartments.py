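"""A/B compartment calling and cross-condition switch classification.

Compartments are called per chromosome from the leading eigenvector of the
Pearson correlation matrix of the observed/expected map, with the sign
oriented against a user-supplied reference activity track (gene density on
real data; the generator's truth track on synthetic data).  Bins with
positive eigenvector value are labeled A, negative B.

Switch classes between two conditions are A2A, B2B, A2B ("deactivated") and
B2A ("activated"); the activation ratio is activated length / deactivated
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .contact_io import BinTable, ContactMatrix
from .matrix_metrics import oe_block

__all__ = [
    "CompartmentProfile",
    "SwitchTrack",
    "ActivationRatio",
    "SWITCH_CLASSES",
    "call_compartments",
    "classify_switch",
    "activation_ratio",
]

SWITCH_CLASSES = ("A2A", "B2B", "A2B", "B2A", "NA")

MIN_BINS_PER_CHROM = 10


@dataclass
class CompartmentProfile:
    """Per-bin leading-eigenvector value (PC1) and A/B label."""

    bins: BinTable
    pc1: np.ndarray            # NaN where NA
    labels: np.ndarray         # "A" | "B" | "NA"

    def accuracy_vs(self, truth_labels: np.ndarray) -> float:
        """Fraction of called (non-NA) bins whose label matches ``truth_labels``."""
        called = self.labels != "NA"
        if not called.any():
            return float("nan")
        return float((self.labels[called] == np.asarray(truth_labels)[called]).mean())


def call_compartments(
    m: ContactMatrix,
    reference_track: np.ndarray,
    min_bins: int = MIN_BINS_PER_CHROM,
) -> CompartmentProfile:
    """Call A/B compartments from a normalized matrix.

    Per chromosome, the observed/expected cis block is reduced to its
    Pearson correlation matrix over unmasked bins and the eigenvector of
    the largest eigenvalue is taken as PC1.  The eigenvector sign is
    arbitrary, so it is flipped if needed to correlate non-negatively with
    ``reference_track`` (one value per bin, higher = more active).
    Chromosomes with fewer than ``min_bins`` unmasked bins are set to NA.
    """
    reference_track = np.asarray(reference_track, dtype=float)
    if reference_track.shape != (m.bins.n_bins,):
        raise ValueError("reference track must have one value per bin")
    pc1 = np.full(m.bins.n_bins, np.nan)
    labels = np.full(m.bins.n_bins, "NA", dtype=object)

    for chrom in m.bins.genome.names:
        lo, hi = m.bins.chrom_range(chrom)
        oe, mask = oe_block(m, chrom)
        free = np.flatnonzero(~mask)
        if free.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; all NA")
            continue
        sub = oe[np.ix_(free, free)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        eigvals, eigvecs = scipy.linalg.eigh(corr)
        vec = eigvecs[:, -1]

        ref = reference_track[lo:hi][free]
        ok = np.isfinite(ref)
        if ok.any() and np.nansum(ref[ok] * vec[ok]) < 0:
            vec = -vec

        chrom_pc1 = np.full(hi - lo, np.nan)
        chrom_pc1[free] = vec
        pc1[lo:hi] = chrom_pc1
        lab = np.full(hi - lo, "NA", dtype=object)
        lab[free] = np.where(vec > 0, "A", np.where(vec < 0, "B", "NA"))
        labels[lo:hi] = lab

    return CompartmentProfile(m.bins, pc1, labels)


@dataclass
class SwitchTrack:
    """Per-bin compartment switch class between two conditions."""

    bins: BinTable
    classes: np.ndarray  # one of SWITCH_CLASSES per bin

    def _bin_lengths(self) -> np.ndarray:
        return (self.bins.ends - self.bins.starts).astype(float)

    def class_length(self, cls: str, chrom: str | None = None) -> float:
        """Total bp length of bins in switch class ``cls`` (optionally per chromosome)."""
        sel = self.classes == cls
        if chrom is not None:
            lo, hi = self.bins.chrom_range(chrom)
            keep = np.zeros(self.bins.n_bins, dtype=bool)
            keep[lo:hi] = True
            sel &= keep
        return float(self._bin_lengths()[sel].sum())

    def fractions(self) -> dict[str, float]:
        """Per-class fraction of the classified (non-NA) genome length."""
        lengths = self._bin_lengths()
        classified = self.classes != "NA"
        total = lengths[classified].sum()
        if total == 0:
            return {c: float("nan") for c in SWITCH_CLASSES if c != "NA"}
        return {
            c: float(lengths[self.classes == c].sum() / total)
            for c in SWITCH_CLASSES
            if c != "NA"
        }

    def fractions_of_genome(self) -> dict[str, float]:
        """Per-class fraction of the total genome length (NA included in denominator)."""
        lengths = self._bin_lengths()
        total = lengths.sum()
        return {
            c: float(lengths[self.classes == c].sum() / total)
            for c in SWITCH_CLASSES
            if c != "NA"
        }

    def class_of_position(self, chrom: str, pos: int) -> str:
        return str(self.classes[self.bins.position_to_bin(chrom, pos)])


def classify_switch(normal: CompartmentProfile, tumor: CompartmentProfile) -> SwitchTrack:
    """Per-bin switch class from the normal profile to the tumor profile."""
    if not normal.bins.same_binning(tumor.bins):
        raise ValueError("profiles are on different bin tables")
    a, b = normal.labels, tumor.labels
    classes = np.full(normal.bins.n_bins, "NA", dtype=object)
    valid = (a != "NA") & (b != "NA")
    classes[valid & (a == "A") & (b == "A")] = "A2A"
    classes[valid & (a == "B") & (b == "B")] = "B2B"
    classes[valid & (a == "A") & (b == "B")] = "A2B"
    classes[valid & (a == "B") & (b == "A")] = "B2A"
    return SwitchTrack(normal.bins, classes)


@dataclass
class ActivationRatio:
    """length(B2A) / length(A2B) with explicit degenerate-case flags."""

    b2a_bp: float
    a2b_bp: float

    @property
    def flag(self) -> str:
        if self.a2b_bp == 0 and self.b2a_bp == 0:
            return "undefined"
        if self.a2b_bp == 0:
            return "infinite"
        return "finite"

    @property
    def value(self) -> float:
        if self.flag == "finite":
            return self.b2a_bp / self.a2b_bp
        return float("inf") if self.flag == "infinite" else float("nan")


def activation_ratio(track: SwitchTrack) -> dict[str, ActivationRatio]:
    """Activation ratio per chromosome plus genome-wide under key 'genome'."""
    out: dict[str, ActivationRatio] = {}
    for chrom in track.bins.genome.names:
        out[chrom] = ActivationRatio(
            track.class_length("B2A", chrom), track.class_length("A2B", chrom)
        )
    out["genome"] = ActivationRatio(track.class_length("B2A"), track.class_length("A2B"))
    return out
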