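"""Character-level literal similarity between symptom names.

Four metrics, each mapping a pair of non-empty strings to [0, 1]:

* ``jaro`` — Jaro similarity: (m/|s| + m/|s'| + (m-t)/m)/3 where m counts
  characters matching within a sliding window and t counts transpositions
  (half the number of matched characters appearing out of order).
* ``jaro_winkler`` — Jaro boosted toward 1 for pairs sharing a prefix:
  JD + min(prefixLength, cap) * p * (1 - JD), default cap 3, p 0.1.
* ``smith_waterman`` — best local alignment under linear gap costs,
  normalized by match * min(|s|, |s'|).
* ``smith_waterman_gotoh`` — local alignment with affine gap costs
  (open + extend), same normalization.

Comparison is by Unicode code point; no case folding or width
normalization is applied (Chinese symptom names have neither).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "JaroWinklerConfig",
    "AlignmentScoring",
    "jaro",
    "jaro_winkler",
    "smith_waterman",
    "smith_waterman_gotoh",
    "literal_scorer",
    "LITERAL_METRICS",
]


@dataclass(frozen=True)
class JaroWinklerConfig:
    """Prefix-boost parameters.

    ``prefix_cap`` is the maximum common-prefix length credited (the scaling
    constant fixed at three); ``prefix_weight`` is the per-character boost,
    constrained so that boosted scores cannot exceed 1.
    """

    prefix_cap: int = 3
    prefix_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.prefix_cap < 0:
            raise ValueError("prefix_cap must be >= 0")
        limit = 1.0 / max(self.prefix_cap, 1)
        if not 0.0 <= self.prefix_weight <= limit:
            raise ValueError(f"prefix_weight must be in [0, {limit}]")


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution and gap scores for the local-alignment metrics.

    ``gap`` is the per-character linear penalty; ``gap_open``/``gap_extend``
    are the affine penalties (a gap of length L costs open + (L-1)*extend).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -0.5
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_extend < self.gap_open:
            raise ValueError("gap_extend must be >= gap_open")

    def substitution(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


_DEFAULT_JW = JaroWinklerConfig()
_DEFAULT_SCORING = AlignmentScoring()


def _require_nonempty(s: str, s2: str) -> None:
    if not s or not s2:
        raise ValueError("literal metrics require non-empty strings")


def _jaro_match_stats(s: str, s2: str) -> tuple[int, int]:
    """Return (m, doubled transposition count) for the Jaro statistic."""
    window = max(max(len(s), len(s2)) // 2 - 1, 0)
    matched2 = [False] * len(s2)
    matches_s: list[str] = []
    for i, ch in enumerate(s):
        lo = max(0, i - window)
        hi = min(len(s2), i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == ch:
                matched2[j] = True
                matches_s.append(ch)
                break
    matches_s2 = [s2[j] for j in range(len(s2)) if matched2[j]]
    half_transpositions = sum(a != b for a, b in zip(matches_s, matches_s2))
    return len(matches_s), half_transpositions


def jaro(s: str, s2: str) -> float:
    """Jaro similarity in [0, 1]; zero matches give 0."""
    _require_nonempty(s, s2)
    m, half_t = _jaro_match_stats(s, s2)
    if m == 0:
        return 0.0
    t = half_t / 2.0
    return (m / len(s) + m / len(s2) + (m - t) / m) / 3.0


def jaro_winkler(s: str, s2: str, cfg: JaroWinklerConfig = _DEFAULT_JW) -> float:
    """Jaro with a common-prefix boost; clamped to [0, 1]."""
    jd = jaro(s, s2)
    prefix = 0
    for a, b in zip(s, s2):
        if a != b or prefix >= cfg.prefix_cap:
            break
        prefix += 1
    score = jd + prefix * cfg.prefix_weight * (1.0 - jd)
    return min(max(score, 0.0), 1.0)


def smith_waterman(s: str, s2: str, scoring: AlignmentScoring = _DEFAULT_SCORING) -> float:
    """Best local-alignment score with linear gaps, scaled to [0, 1].

    The raw dynamic-programming optimum (cells floored at 0) is divided by
    match * min(|s|, |s'|), the score of a perfect alignment of the shorter
    string, so every literal metric shares one threshold scale.
    """
    _require_nonempty(s, s2)
    gap = scoring.gap
    prev = [0.0] * (len(s2) + 1)
    best = 0.0
    for i in range(1, len(s) + 1):
        cur = [0.0] * (len(s2) + 1)
        ci = s[i - 1]
        for j in range(1, len(s2) + 1):
            val = max(
                0.0,
                prev[j - 1] + scoring.substitution(ci, s2[j - 1]),
                prev[j] + gap,
                cur[j - 1] + gap,
            )
            cur[j] = val
            if val > best:
                best = val
        prev = cur
    return min(best / (scoring.match * min(len(s), len(s2))), 1.0)


def smith_waterman_gotoh(
    s: str, s2: str, scoring: AlignmentScoring = _DEFAULT_SCORING
) -> float:
    """Local alignment with affine gap costs (Gotoh three-state DP).

    A gap of length L costs gap_open + (L-1)*gap_extend.  With
    gap_open == gap_extend == gap this reduces exactly to
    :func:`smith_waterman`.  Normalization as in :func:`smith_waterman`.
    """
    _require_nonempty(s, s2)
    neg_inf = float("-inf")
    n2 = len(s2)
    h_prev = [0.0] * (n2 + 1)
    f_prev = [neg_inf] * (n2 + 1)  # gap in s2 (vertical)
    best = 0.0
    for i in range(1, len(s) + 1):
        h_cur = [0.0] * (n2 + 1)
        f_cur = [neg_inf] * (n2 + 1)
        e = neg_inf  # gap in s (horizontal), current row
        ci = s[i - 1]
        for j in range(1, n2 + 1):
            e = max(h_cur[j - 1] + scoring.gap_open, e + scoring.gap_extend)
            f_cur[j] = max(h_prev[j] + scoring.gap_open, f_prev[j] + scoring.gap_extend)
            val = max(0.0, h_prev[j - 1] + scoring.substitution(ci, s2[j - 1]), e, f_cur[j])
            h_cur[j] = val
            if val > best:
                best = val
        h_prev, f_prev = h_cur, f_cur
    return min(best / (scoring.match * min(len(s), len(s2))), 1.0)


#: Metric name tokens used in configs and on the command line.
LITERAL_METRICS = ("jd", "jwd", "swd", "swgd")


def literal_scorer(
    metric: str,
    jw_cfg: JaroWinklerConfig = _DEFAULT_JW,
    scoring: AlignmentScoring = _DEFAULT_SCORING,
):
    """Return a ``(s, s2) -> score`` callable for a metric name token."""
    if metric == "jd":
        return jaro
    if metric == "jwd":
        return lambda s, s2: jaro_winkler(s, s2, jw_cfg)
    if metric == "swd":
        return lambda s, s2: smith_waterman(s, s2, scoring)
    if metric == "swgd":
        return lambda s, s2: smith_waterman_gotoh(s, s2, scoring)
    raise ValueError(f"unknown literal metric {metric!r}; expected one of {LITERAL_METRICS}")
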