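"""Independent brute-force oracles, written in plain Python loops so they
share no code path with the package implementation."""

from __future__ import annotations


def naive_base_scores(seq: str) -> list[int]:
    """Run-capped per-base scores by explicit character walking."""
    seq = seq.upper().replace("U", "T")
    scores = [0] * len(seq)
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch in "GC":
            j = i
            while j < len(seq) and seq[j] == ch:
                j += 1
            val = min(j - i, 4) * (1 if ch == "G" else -1)
            for k in range(i, j):
                scores[k] = val
            i = j
        else:
            i += 1
    return scores


def naive_window_means(seq: str, w: int) -> list[float]:
    scores = naive_base_scores(seq)
    return [sum(scores[k : k + w]) / w for k in range(len(scores) - w + 1)]


def naive_call_pqs(seq: str, w: int, threshold: float) -> list[tuple[int, int, str, float]]:
    """Exhaustive window enumeration + interval union, one sign at a time.

    Returns (start, end, strand, score) tuples sorted by (start, strand).
    """
    scores = naive_base_scores(seq)
    means = naive_window_means(seq, w)
    out = []
    for strand, qualify in (("+", lambda m: m >= threshold), ("-", lambda m: m <= -threshold)):
        intervals = [(k, k + w) for k, m in enumerate(means) if qualify(m)]
        merged: list[list[int]] = []
        for a, b in intervals:
            if merged and a <= merged[-1][1]:  # overlap or touch
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            out.append((a, b, strand, sum(scores[a:b]) / (b - a)))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


def naive_kruskal_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H via explicit mid-ranking."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    # mid-ranks with ties
    ranks: dict[float, float] = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    h = 12.0 / (n * (n + 1)) * sum(
        sum(ranks[v] for v in g) ** 2 / len(g) for g in groups
    ) - 3 * (n + 1)
    # tie correction
    tie_sum = 0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        tie_sum += t**3 - t
        i = j
    denom = 1 - tie_sum / (n**3 - n)
    return h / denom
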