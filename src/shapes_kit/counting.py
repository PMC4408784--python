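"""Per-position termination counts, coverage and termination-coverage ratios.

Conventions (isolated here so the off-by-one choices stay auditable):

* A fragment with left end ``p > 1`` reports a reverse-transcription stop at
  position ``p - 1`` — the blocked (modified) position, read in the
  direction of cDNA synthesis.
* A fragment with ``left == 1`` reached the RNA 5' end and is a *run-off*;
  it is kept in a separate bucket, never inside the per-position vector
  (TSV output emits it as position 0).
* A fragment (left=p, right=q) covers position i iff i is in
  {p-1} ∪ {p..q} — i.e. every position it spans plus the stop it reports —
  and the priming distance q - i is at least ``min_priming_distance``
  (default 100 nt), which removes the size-selection bias against
  positions close to the priming site.
* Position L always receives zero termination counts: no fragment can have
  left end L + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .fragments import FragmentRecord

DEFAULT_MIN_PRIMING_DISTANCE = 100


@dataclass
class TerminationProfile:
    """Per-position RT-stop counts plus the separate run-off bucket."""

    rna_id: str
    counts: np.ndarray  # int vector, length L; counts[i-1] = stops at position i
    runoff_count: int
    n_fragments: int

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.runoff_count


@dataclass
class CoverageProfile:
    rna_id: str
    coverage: np.ndarray  # int vector, length L
    min_priming_distance: int = DEFAULT_MIN_PRIMING_DISTANCE

    @property
    def length(self) -> int:
        return len(self.coverage)


@dataclass
class TcrProfile:
    """Termination-coverage ratio; NaN marks positions with zero coverage."""

    rna_id: str
    tcr: np.ndarray  # float vector, length L, values in [0,1] or NaN
    params: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.tcr)


def _as_arrays(fragments: list[FragmentRecord], L: int) -> tuple[str, np.ndarray, np.ndarray]:
    if not fragments:
        raise DataError("empty fragment list")
    rna_ids = {f.rna_id for f in fragments}
    if len(rna_ids) != 1:
        raise DataError(f"fragments span multiple RNAs: {sorted(rna_ids)}")
    lefts = np.fromiter((f.left for f in fragments), dtype=np.int64, count=len(fragments))
    rights = np.fromiter((f.right for f in fragments), dtype=np.int64, count=len(fragments))
    if rights.max() > L:
        raise DataError(f"fragment right end {rights.max()} exceeds L={L}")
    return rna_ids.pop(), lefts, rights


def termination_counts(
    fragments: list[FragmentRecord],
    L: int,
    min_priming_distance: int | None = None,
) -> TerminationProfile:
    """Sum RT stops per position: left end p contributes to position p - 1.

    When ``min_priming_distance`` is given, body stops are only counted if
    the priming distance right - (left - 1) meets it — the same rule the
    coverage denominator applies — so that the resulting TCR numerator never
    exceeds its denominator. Run-off fragments are always tallied.
    """
    rna_id, lefts, rights = _as_arrays(fragments, L)
    runoff = int((lefts == 1).sum())
    body = lefts > 1
    if min_priming_distance is not None:
        body &= (rights - (lefts - 1)) >= min_priming_distance
    counts = np.bincount(lefts[body] - 2, minlength=L).astype(np.int64)
    return TerminationProfile(rna_id, counts, runoff, n_fragments=len(fragments))


def coverage(
    fragments: list[FragmentRecord],
    L: int,
    min_priming_distance: int = DEFAULT_MIN_PRIMING_DISTANCE,
) -> CoverageProfile:
    """Distance-filtered coverage via an interval difference array.

    The covered set {p-1} ∪ {p..q} is the contiguous run [p-1, q]; the
    distance rule caps it at q - min_priming_distance.
    """
    rna_id, lefts, rights = _as_arrays(fragments, L)
    lo = np.maximum(lefts - 1, 1)
    hi = rights - min_priming_distance
    keep = hi >= lo
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, lo[keep] - 1, 1)
    np.add.at(diff, hi[keep], -1)
    return CoverageProfile(rna_id, np.cumsum(diff[:L]), min_priming_distance)


def tcr(termination: TerminationProfile, cov: CoverageProfile) -> TcrProfile:
    """Per-position termination-coverage ratio counts(i) / coverage(i).

    Missing (NaN) where coverage is zero. Termination events are part of
    coverage by construction when the distance rule admits them, so
    counts > coverage indicates mismatched inputs and raises.
    """
    if termination.rna_id != cov.rna_id:
        raise DataError(
            f"profile RNA mismatch: {termination.rna_id!r} vs {cov.rna_id!r}"
        )
    if termination.length != cov.length:
        raise DataError(
            f"profile length mismatch: {termination.length} vs {cov.length}"
        )
    bad = termination.counts > cov.coverage
    if bad.any():
        i = int(np.flatnonzero(bad)[0]) + 1
        raise DataError(
            f"termination count exceeds coverage at position {i} "
            f"({int(termination.counts[i - 1])} > {int(cov.coverage[i - 1])}); "
            "inputs appear mismatched (did the numerator use the same "
            "priming-distance rule?)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(
            cov.coverage > 0, termination.counts / cov.coverage, np.nan
        )
    return TcrProfile(
        termination.rna_id,
        values,
        params={"min_priming_distance": cov.min_priming_distance},
    )


def tcr_from_fragments(
    fragments: list[FragmentRecord],
    L: int,
    min_priming_distance: int = DEFAULT_MIN_PRIMING_DISTANCE,
) -> TcrProfile:
    """Convenience: distance-consistent TCR straight from a fragment list."""
    term = termination_counts(fragments, L, min_priming_distance)
    return tcr(term, coverage(fragments, L, min_priming_distance))


def runoff_fraction(profile: TerminationProfile) -> float:
    """Fraction of fragments that ran off to the RNA 5' end.

    High run-off fractions are the signature of unselected stop-based
    probing; selection should push this down sharply.
    """
    total = profile.total
    if total == 0:
        raise DataError("run-off fraction undefined for zero fragments")
    return profile.runoff_count / total


def spike_ratio(
    fragments: list[FragmentRecord], rna_a: str, rna_b: str
) -> float:
    """Ratio of mapped-fragment counts between two spike-in RNAs (a / b).

    Returns inf when rna_b has zero fragments but rna_a does not; both the
    numerator and denominator RNA must be present in the fragment set's
    reference universe (i.e. appear at least once between them).
    """
    n_a = sum(1 for f in fragments if f.rna_id == rna_a)
    n_b = sum(1 for f in fragments if f.rna_id == rna_b)
    if n_a == 0 and n_b == 0:
        raise DataError(f"neither {rna_a!r} nor {rna_b!r} has mapped fragments")
    if n_b == 0:
        return float("inf")
    return n_a / n_b


def write_profile_tsv(
    path,
    termination: TerminationProfile,
    cov: CoverageProfile | None = None,
    ratio: TcrProfile | None = None,
) -> None:
    """TSV profile dump: rna_id, position, termination_count, coverage, tcr.

    The run-off bucket is written as position 0 with empty coverage/tcr.
    """
    L = termination.length
    with open(path, "w") as fh:
        fh.write("rna_id\tposition\ttermination_count\tcoverage\ttcr\n")
        fh.write(f"{termination.rna_id}\t0\t{termination.runoff_count}\t\t\n")
        for i in range(L):
            c = "" if cov is None else str(int(cov.coverage[i]))
            if ratio is None or np.isnan(ratio.tcr[i]):
                t = ""
            else:
                t = f"{ratio.tcr[i]:.6g}"
            fh.write(
                f"{termination.rna_id}\t{i + 1}\t{int(termination.counts[i])}\t{c}\t{t}\n"
            )
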