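"""Cohort percentile ranks for expression and DNA-RNA integration.

Expression is compared within a reference cohort as the midrank percentile
of the sample's TPM for a gene. A copy-number gain whose gene is highly
expressed relative to the cohort is nominated as a driver candidate; a
gain whose gene is lowly expressed is a likely passenger. Expression can be
strongly influenced by a tumor's location, so every expression-based call
carries a caveat string and no call is made from expression alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from mtb_interpret.scars import CNACall, CNACallType

#: attached verbatim to every expression-based call in reports
EXPRESSION_CAVEAT = (
    "Expression-based calls can be strongly influenced by a tumor's location "
    "and microenvironment; interpret relative ranks with caution."
)


@dataclass
class ExpressionProfile:
    sample_id: str
    tpm: dict[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.tpm.items():
            if value < 0:
                raise ValueError(f"TPM must be >= 0, got {value} for {gene}")


@dataclass(frozen=True)
class CohortRank:
    gene: str
    tpm: float
    percentile: float
    cohort_n: int


class Verdict(str, enum.Enum):
    DRIVER_CANDIDATE = "DRIVER_CANDIDATE"
    PASSENGER = "PASSENGER"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class IntegratedCall:
    gene: str
    cna_call: CNACallType
    percentile: float
    verdict: Verdict
    caveat: str = EXPRESSION_CAVEAT


def cohort_percentile(
    profile: ExpressionProfile,
    cohort: Sequence[ExpressionProfile],
    gene: str,
    include_self: bool = True,
) -> CohortRank:
    """Midrank percentile of the sample's TPM within the cohort.

    percentile = 100 * (values strictly below + 0.5 * ties) / n. Ties are
    averaged (midrank), so a value equal to every cohort value ranks at the
    50th percentile. By default the index sample is included in its own
    cohort, which keeps ranks stable for small cohorts.
    """
    if gene not in profile.tpm:
        raise KeyError(f"gene {gene!r} not in sample profile")
    values = [p.tpm[gene] for p in cohort if gene in p.tpm and p.sample_id != profile.sample_id]
    if len(values) < 2:
        raise ValueError(f"gene {gene!r} present in fewer than 2 cohort samples")
    tpm = profile.tpm[gene]
    if include_self:
        values.append(tpm)
    below = sum(1 for v in values if v < tpm)
    ties = sum(1 for v in values if v == tpm)
    n = len(values)
    percentile = 100.0 * (below + 0.5 * ties) / n
    return CohortRank(gene=gene, tpm=tpm, percentile=percentile, cohort_n=n)


def overexpression_call(rank: CohortRank, threshold_pct: float = 90.0) -> bool:
    """Overexpressed iff the cohort percentile reaches the threshold.

    Used to nominate immunotherapy / antibody-drug-conjugate targets from
    expression (e.g. cell-surface target transcripts)."""
    return rank.percentile >= threshold_pct


def integrate_cna_expression(
    cna: CNACall,
    rank: CohortRank,
    hi: float = 75.0,
    lo: float = 25.0,
) -> IntegratedCall:
    """Driver/passenger nomination for an amplified or gained gene.

    High cohort expression (percentile >= hi) supports a driver role; low
    expression (<= lo) marks the gain as a likely passenger; in between the
    call is indeterminate.
    """
    if cna.call not in (CNACallType.AMP, CNACallType.GAIN):
        raise ValueError(
            f"DNA-RNA integration applies to AMP/GAIN calls, got {cna.call}"
        )
    if rank.percentile >= hi:
        verdict = Verdict.DRIVER_CANDIDATE
    elif rank.percentile <= lo:
        verdict = Verdict.PASSENGER
    else:
        verdict = Verdict.INDETERMINATE
    return IntegratedCall(
        gene=cna.gene,
        cna_call=cna.call,
        percentile=rank.percentile,
        verdict=verdict,
    )


def read_tpm_matrix(path: str | Path) -> list[ExpressionProfile]:
    """Read a genes x samples TPM matrix TSV into per-sample profiles."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative TPM values")
    return [
        ExpressionProfile(sample_id=str(col), tpm=df[col].to_dict())
        for col in df.columns
    ]


def write_tpm_matrix(profiles: Sequence[ExpressionProfile], path: str | Path) -> None:
    df = pd.DataFrame({p.sample_id: p.tpm for p in profiles})
    df.to_csv(path, sep="\t", index_label="gene")
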