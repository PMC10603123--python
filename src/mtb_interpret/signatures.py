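"""SBS-96 mutation catalogs and signature exposure refitting.

A single-base-substitution catalog counts SNVs in 96 classes: six
pyrimidine-centric substitutions (C>A, C>G, C>T, T>A, T>C, T>G) times the
4 x 4 flanking-base combinations. SNVs reported on the purine strand are
reverse-complemented into the pyrimidine classes. Exposures to a known
signature matrix are refit by non-negative least squares:

    minimise || counts - S . e ||_2   subject to  e >= 0

which is deterministic for fixed input; per-signature fractions are the
exposures normalised to the catalog total. De-novo signature extraction is
out of scope — refitting against a supplied matrix (e.g. COSMIC) only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def context_labels() -> list[str]:
    """The 96 context labels in canonical COSMIC order: A[C>A]A, A[C>A]C, ..."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


CONTEXT_LABELS = tuple(context_labels())
_LABEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def classify_snv(ref: str, alt: str, trinucleotide: str) -> str:
    """Map an SNV to its pyrimidine-centric SBS-96 label.

    ``trinucleotide`` is the reference-strand context with ``ref`` as its
    central base; purine-reference SNVs are strand-collapsed.
    """
    ref, alt = ref.upper(), alt.upper()
    tri = trinucleotide.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(tri) != 3 or tri[1] != ref:
        raise ValueError(f"context {tri!r} does not center on ref base {ref!r}")
    if ref in ("G", "A"):  # purine reference: collapse to pyrimidine strand
        ref, alt, tri = _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(tri)
    label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    if label not in _LABEL_INDEX:
        raise ValueError(f"invalid SBS-96 label {label!r}")
    return label


@dataclass
class MutationCatalog:
    """Counts over the 96 trinucleotide substitution classes."""

    counts: np.ndarray
    skipped_non_snv: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 bins, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name="count")


@dataclass
class SignatureMatrix:
    """96 x K matrix of per-context probabilities, one column per signature."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.names = tuple(self.names)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError(f"signature matrix must be 96 x K, got {self.matrix.shape}")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        """Read a COSMIC-format TSV: first column the 96 context labels,
        remaining columns one signature each. Rows may be in any order."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CONTEXT_LABELS) - set(df.index)
        if missing:
            raise ValueError(f"signature TSV missing contexts: {sorted(missing)[:3]}...")
        df = df.loc[list(CONTEXT_LABELS)]
        return cls(matrix=df.to_numpy(), names=tuple(df.columns))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=list(CONTEXT_LABELS), columns=list(self.names)
        ).to_csv(path, sep="\t", index_label="Type")


@dataclass
class ExposureResult:
    """NNLS exposures (mutation counts), normalised fractions, and residual."""

    exposures: np.ndarray
    fractions: np.ndarray | None
    residual_norm: float
    names: tuple[str, ...]

    def fraction_of(self, name: str) -> float:
        if self.fractions is None:
            raise ValueError("fractions undefined for an empty catalog")
        return float(self.fractions[self.names.index(name)])


def build_catalog(
    snvs: Sequence,
    context_source,
) -> MutationCatalog:
    """Build an SBS-96 catalog from SNVs.

    ``context_source`` is either a mapping from ``chrom:pos`` to the
    reference-strand trinucleotide, or an indexed FASTA (pyfaidx.Fasta-like)
    from which contexts are looked up. Non-SNVs are skipped and counted in
    ``skipped_non_snv``.
    """
    counts = np.zeros(96)
    skipped = 0
    for var in snvs:
        if len(var.ref) != 1 or len(var.alt) != 1:
            skipped += 1
            continue
        tri = _lookup_context(context_source, var)
        label = classify_snv(var.ref, var.alt, tri)
        counts[_LABEL_INDEX[label]] += 1
    return MutationCatalog(counts=counts, skipped_non_snv=skipped)


def _lookup_context(context_source, var) -> str:
    key = f"{var.interval.chrom}:{var.interval.start}"
    if isinstance(context_source, Mapping):
        if key not in context_source:
            raise KeyError(f"no trinucleotide context for {key}")
        return str(context_source[key])
    # indexed FASTA: 1-based position, need pos-1 .. pos+1
    chrom, pos = var.interval.chrom, var.interval.start
    seq = context_source[chrom][pos - 2 : pos + 1]
    return str(seq).upper()


def fit_exposures(catalog: MutationCatalog, sigs: SignatureMatrix) -> ExposureResult:
    """Refit signature exposures by non-negative least squares.

    For an all-zero catalog the exposures are zero and fractions are
    undefined (None).
    """
    if catalog.total == 0:
        return ExposureResult(
            exposures=np.zeros(sigs.k),
            fractions=None,
            residual_norm=0.0,
            names=sigs.names,
        )
    exposures, residual = nnls(sigs.matrix, catalog.counts)
    total = exposures.sum()
    fractions = exposures / total if total > 0 else None
    return ExposureResult(
        exposures=exposures,
        fractions=fractions,
        residual_norm=float(residual),
        names=sigs.names,
    )


def exposures_to_frame(result: ExposureResult) -> pd.DataFrame:
    """Tabulate exposures and fractions for TSV output."""
    return pd.DataFrame(
        {
            "signature": list(result.names),
            "exposure": result.exposures,
            "fraction": (
                result.fractions if result.fractions is not None else np.nan
            ),
        }
    )
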