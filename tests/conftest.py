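"""Shared test fixtures and independent oracles.

The scar-metric oracles here deliberately avoid the package's interval
arithmetic: fixture profiles align to whole-megabase boundaries, so an
exhaustive per-megabase array scan reproduces LOH runs and state switches
exactly and independently.
"""

from __future__ import annotations

import numpy as np
import pytest

from mtb_interpret import fixtures as fx

MBP = 1_000_000


@pytest.fixture(scope="session")
def toy_genome() -> fx.ToyGenome:
    return fx.ToyGenome()


@pytest.fixture(scope="session")
def fixture_sigs():
    return fx.fixture_signatures()


@pytest.fixture(
    scope="session",
    params=[
        ("SILENT", 1),
        ("HRD_LIKE", 1),
        ("HRD_LIKE", 2),
        ("HRD_LIKE", 3),
        ("AMPLIFIED_12q_LIKE", 1),
    ],
    ids=lambda p: f"{p[0]}-seed{p[1]}",
)
def segment_fixture(request) -> fx.SegmentFixture:
    kind, seed = request.param
    return fx.gen_segments(fx.FixtureSpec(seed=seed, profile_kind=kind))


# ---------------------------------------------------------------------------
# Per-megabase array oracle for scar metrics
# ---------------------------------------------------------------------------


def profile_to_arrays(segments, genome: fx.ToyGenome):
    """Expand a segment list into per-Mbp (total, minor) state arrays.

    Bin i of a chromosome covers bases [i*1Mbp + 1, (i+1)*1Mbp]; fixture
    segments align to these boundaries. Uncovered bins hold -1.
    """
    arrays = {}
    for chrom in genome.chromosomes:
        n = chrom.length // MBP
        total = np.full(n, -1, dtype=int)
        minor = np.full(n, -1, dtype=int)
        arrays[chrom.name] = (total, minor)
    for seg in segments:
        total, minor = arrays[seg.interval.chrom]
        first = (seg.interval.start - 1) // MBP
        last = seg.interval.end // MBP  # end is at a bin boundary
        total[first:last] = round(seg.total_cn)
        minor[first:last] = -1 if seg.minor_cn is None else round(seg.minor_cn)
    return arrays


def oracle_hrd_loh(segments, genome: fx.ToyGenome, min_mbp: int = 15) -> int:
    """Exhaustive scan: count LOH runs > min_mbp not spanning the chromosome."""
    arrays = profile_to_arrays(segments, genome)
    count = 0
    for chrom in genome.chromosomes:
        total, minor = arrays[chrom.name]
        n = len(total)
        is_loh = (minor == 0) & (total >= 1)
        i = 0
        while i < n:
            if not is_loh[i]:
                i += 1
                continue
            j = i
            while j < n and is_loh[j]:
                j += 1
            run_mbp = j - i
            if run_mbp > min_mbp and not (i == 0 and j == n):
                count += 1
            i = j
    return count


def _arm_bins(chrom: fx.ToyChromosome):
    """(start_bin, end_bin) half-open bin ranges of the p and q arms."""
    p = (0, chrom.p_end // MBP)
    q = ((chrom.q_start - 1) // MBP, chrom.length // MBP)
    return p, q


def oracle_lst(
    segments, genome: fx.ToyGenome, smooth_mbp: int = 3, min_flank_mbp: int = 10
) -> int:
    """Exhaustive per-arm scan: smooth sub-3-Mbp runs away, count switches
    with both flanks >= min_flank_mbp."""
    arrays = profile_to_arrays(segments, genome)
    count = 0
    for chrom in genome.chromosomes:
        total, minor = arrays[chrom.name]
        for start, end in _arm_bins(chrom):
            states = [
                (total[i], minor[i]) for i in range(start, end) if total[i] >= 0
            ]
            # collapse into runs
            runs: list[tuple[tuple, int]] = []
            for s in states:
                if runs and runs[-1][0] == s:
                    runs[-1] = (s, runs[-1][1] + 1)
                else:
                    runs.append((s, 1))
            # drop short runs, re-merge
            smoothed: list[tuple[tuple, int]] = []
            for s, ln in runs:
                if ln < smooth_mbp:
                    continue
                if smoothed and smoothed[-1][0] == s:
                    smoothed[-1] = (s, smoothed[-1][1] + ln)
                else:
                    smoothed.append((s, ln))
            for (sa, la), (sb, lb) in zip(smoothed, smoothed[1:]):
                if sa != sb and la >= min_flank_mbp and lb >= min_flank_mbp:
                    count += 1
    return count


def oracle_ploidy(segments) -> float:
    """Brute-force length-weighted mean total copy number."""
    num = 0.0
    den = 0
    for seg in segments:
        if seg.interval.chrom in ("X", "Y"):
            continue
        ln = seg.interval.end - seg.interval.start + 1
        num += ln * seg.total_cn
        den += ln
    return num / den
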