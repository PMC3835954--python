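"""Shared contiguous k-mer match statistics and the activity prediction rule.

The specificity statistic for an insecticidal dsRNA trigger against a
non-target ortholog is the number m of shared contiguous k-nt windows
(k = 21 by default) together with the longest shared contiguous run ℓ.
Biological activity is predicted only when at least one shared 21-nt window
exists (equivalently ℓ ≥ 21): shorter matches, down to single 19-nt runs,
have shown no activity in sensitive species.

Two counting modes are provided:

* aligned mode (the default for ortholog reports): windows are counted over
  the columns of the pairwise alignment; a window matches when all k columns
  are identical non-gap, non-N matches. Overlapping windows all count.
* substring mode (position-free screening of unaligned sequences): a trigger
  window counts when its k-mer occurs verbatim anywhere in the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import GAP, AlignedPair, _is_identity_column
from .errors import ValidationError
from .seq_io import SequenceRecord

DEFAULT_K = 21


@dataclass(frozen=True)
class MatchProfile:
    """Shared-window summary: window length k, window count m, longest run ℓ.

    ``window_starts`` are 1-based start columns (aligned mode) or 1-based
    trigger positions (substring mode) of the matching windows.
    """

    k: int
    m: int
    longest_run: int
    window_starts: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.m != len(self.window_starts):
            raise ValidationError("m inconsistent with window_starts")
        if (self.m >= 1) != (self.longest_run >= self.k):
            raise ValidationError("m >= 1 must hold exactly when longest_run >= k")


@dataclass(frozen=True)
class ActivityCall:
    predicted_active: bool
    rationale: str


def _column_matches(pair: AlignedPair) -> list[bool]:
    return [
        _is_identity_column(x, y) for x, y in zip(pair.row_a, pair.row_b)
    ]


def _runs(matches: list[bool]):
    """Yield (start_index_0based, length) for each maximal run of True."""
    start = None
    for i, ok in enumerate(matches):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            yield start, i - start
            start = None
    if start is not None:
        yield start, len(matches) - start


def shared_window_count(pair: AlignedPair, k: int = DEFAULT_K) -> MatchProfile:
    """Count shared contiguous k-nt windows over alignment columns.

    m is the number of start columns t (1-based) such that columns
    t..t+k-1 are all identical non-gap matches; every matching start
    position counts, so overlapping windows are not collapsed.
    """
    L = pair.n_columns
    if not 1 <= k <= L:
        raise ValidationError(f"k={k} outside [1, {L}]")
    matches = _column_matches(pair)
    starts: list[int] = []
    longest = 0
    for run_start, run_len in _runs(matches):
        longest = max(longest, run_len)
        # a run of length r contains r-k+1 window start positions
        starts.extend(range(run_start + 1, run_start + run_len - k + 2))
    starts.sort()
    return MatchProfile(k=k, m=len(starts), longest_run=longest, window_starts=tuple(starts))


def longest_shared_run(pair: AlignedPair) -> int:
    """Length in nt of the longest run of consecutive identical non-gap columns."""
    matches = _column_matches(pair)
    return max((length for _, length in _runs(matches)), default=0)


def substring_match_count(
    trigger: SequenceRecord,
    target: SequenceRecord,
    k: int = DEFAULT_K,
    scan_revcomp: bool = False,
) -> MatchProfile:
    """Position-free screen: trigger k-mers occurring anywhere in the target.

    m counts distinct trigger window start positions whose k-mer is an exact
    substring of the target in sense orientation (a dsRNA trigger already
    carries both strands; set ``scan_revcomp`` to additionally scan the
    reverse complement). Windows containing N never match.
    """
    if k > len(trigger) or k > len(target):
        raise ValidationError(f"k={k} exceeds a sequence length")
    if k < 1:
        raise ValidationError("k must be >= 1")
    targets = [target.residues]
    if scan_revcomp:
        comp = str.maketrans("ACGTN", "TGCAN")
        targets.append(target.residues.translate(comp)[::-1])
    kmers: set[str] = set()
    for t in targets:
        for i in range(len(t) - k + 1):
            w = t[i : i + k]
            if "N" not in w:
                kmers.add(w)
    starts = []
    seq = trigger.residues
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w and w in kmers:
            starts.append(i + 1)
    # longest run: longest stretch of consecutive trigger positions covered
    # by matching windows, i.e. maximal chain of consecutive starts + k - 1
    longest = 0
    chain = 0
    prev = None
    for s in starts:
        chain = chain + 1 if prev is not None and s == prev + 1 else 1
        longest = max(longest, chain + k - 1)
        prev = s
    return MatchProfile(k=k, m=len(starts), longest_run=longest, window_starts=tuple(starts))


def predict_activity(profile: MatchProfile, threshold_k: int = DEFAULT_K) -> ActivityCall:
    """Predict biological activity from the ≥1 shared k-nt window rule."""
    if profile.k != threshold_k:
        raise ValidationError(
            f"profile computed at k={profile.k}, prediction requested at k={threshold_k}"
        )
    active = profile.m >= 1
    rationale = (
        f"{profile.m} shared {profile.k}-nt window(s); "
        f"longest shared run {profile.longest_run} nt; "
        f"predicted {'active' if active else 'not active'} "
        f"(rule: >= 1 shared {threshold_k}-nt contiguous match)"
    )
    return ActivityCall(predicted_active=active, rationale=rationale)
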