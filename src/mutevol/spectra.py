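"""Contextual mutation spectra.

Single-nucleotide mutations are binned into 96 trinucleotide classes: six
pyrimidine-centered substitution outcomes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the four possible 5' and 3' flanking bases.  Mutations whose
reference base is a purine are reverse-complemented (together with their
flanks) before labeling, so the spectrum is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MutationCall, ReferenceGenome, log_stage

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PURINES = frozenset("AG")

#: the six focal outcomes, in conventional block order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"),
    ("C", "G"),
    ("C", "T"),
    ("T", "A"),
    ("T", "C"),
    ("T", "G"),
)

#: canonical ordering of the 96 class labels: substitution blocks, then
#: 5' flank (major) and 3' flank (minor) alphabetically
CLASS_LABELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

SIX_CLASS_LABELS: tuple[str, ...] = tuple(
    f"{ref}>{alt}" for ref, alt in SUBSTITUTIONS
)

_CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


def context_class(
    ref_base: str, alt_base: str, five_prime: str, three_prime: str
) -> str:
    """Return the pyrimidine-centered 96-class label of a substitution.

    If ``ref_base`` is a purine, the substitution and both flanks are
    reverse-complemented first (the flanks swap roles under the flip).
    """
    bases = (ref_base, alt_base, five_prime, three_prime)
    for b in bases:
        if b not in COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if ref_base in PURINES:
        ref_base = COMPLEMENT[ref_base]
        alt_base = COMPLEMENT[alt_base]
        five_prime, three_prime = (
            COMPLEMENT[three_prime],
            COMPLEMENT[five_prime],
        )
    return f"{five_prime}[{ref_base}>{alt_base}]{three_prime}"


@dataclass
class ContextSpectrum:
    """96-class mutation counts with the 6-class aggregation derived."""

    counts: np.ndarray  # shape (96,), non-negative integers
    n_skipped: int = 0
    errors: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return CLASS_LABELS

    @property
    def six_class(self) -> np.ndarray:
        """Aggregate over flanks: one count per substitution outcome."""
        return self.counts.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(96)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": CLASS_LABELS,
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )

    def __add__(self, other: "ContextSpectrum") -> "ContextSpectrum":
        return ContextSpectrum(
            self.counts + other.counts,
            n_skipped=self.n_skipped + other.n_skipped,
        )


def build_spectrum(
    snm_calls: list[MutationCall], genome: ReferenceGenome
) -> ContextSpectrum:
    """Count the 96 contextual classes over a set of SNM calls.

    Calls at sequence ends, with a non-ACGT base in the trinucleotide, or
    whose REF disagrees with the genome are skipped; mismatches are kept as
    per-call error records.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_skipped = 0
    errors = []
    for call in snm_calls:
        if call.mclass != "SNM":
            continue
        seq = genome[call.chrom]
        i = call.pos - 1  # to 0-based
        if i < 1 or i > len(seq) - 2:
            n_skipped += 1
            continue
        ref = seq[i]
        if ref != call.ref:
            errors.append(
                (call.line_id, call.chrom, call.pos, call.ref, ref)
            )
            n_skipped += 1
            continue
        five, three = seq[i - 1], seq[i + 1]
        try:
            label = context_class(ref, call.alt, five, three)
        except ValueError:
            n_skipped += 1
            continue
        counts[_CLASS_INDEX[label]] += 1
    spectrum = ContextSpectrum(counts, n_skipped=n_skipped, errors=errors)
    log_stage("spectrum", len(snm_calls), spectrum.total)
    return spectrum


def spectrum_matrix(
    spectra: dict[str, ContextSpectrum], normalize: bool = False
) -> pd.DataFrame:
    """Stack per-sample spectra into a 96 x samples matrix (rows = classes)."""
    data = {
        name: (s.frequencies if normalize else s.counts)
        for name, s in spectra.items()
    }
    return pd.DataFrame(data, index=list(CLASS_LABELS))
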