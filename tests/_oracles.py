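"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementations: the Fisher
oracle works in exact integer arithmetic on enumerated tables, and the
Mann-Whitney oracle enumerates every assignment of the pooled values to the
two groups.
"""

from __future__ import annotations

import itertools
from math import comb


def fisher_3x2_oracle(table) -> float:
    """Exact 3x2 Fisher p by integer enumeration over the two free cells.

    Probabilities share the denominator C(N, c0); comparing integer
    numerators with the same 1e-7 relative slack as the implementation keeps
    the tie handling exact.
    """
    (a0, b0), (a1, b1), (a2, b2) = [[int(x) for x in row] for row in table]
    r = [a0 + b0, a1 + b1, a2 + b2]
    c0 = a0 + a1 + a2
    n = sum(r)
    if n == 0:
        raise ValueError("degenerate table")
    num_obs = comb(r[0], a0) * comb(r[1], a1) * comb(r[2], a2)
    total = 0
    for a in range(min(r[0], c0) + 1):
        for b in range(min(r[1], c0 - a) + 1):
            cc = c0 - a - b
            if cc > r[2]:
                continue
            num = comb(r[0], a) * comb(r[1], b) * comb(r[2], cc)
            # num <= num_obs * (1 + 1e-7), exactly in integers
            if num * 10**7 <= num_obs * (10**7 + 1):
                total += num
    return total / comb(n, c0)


def fisher_3x2_oracle_by_margins(row_margins, col_margins):
    """All attainable 3x2 tables with the given margins and their exact p's.

    Yields ``(table, p)`` pairs.  Probabilities share the denominator
    C(N, c0), so sorting the integer numerators once and binary-searching the
    slack-adjusted cutoff gives every table's p in O(k log k) total; this is
    what makes an exhaustive scan over every small table affordable.
    """
    r0, r1, r2 = row_margins
    c0, _ = col_margins
    n = r0 + r1 + r2
    denom = comb(n, c0)
    entries = []  # (numerator, a, b)
    for a in range(min(r0, c0) + 1):
        for b in range(min(r1, c0 - a) + 1):
            cc = c0 - a - b
            if cc > r2:
                continue
            entries.append((comb(r0, a) * comb(r1, b) * comb(r2, cc), a, b))
    nums = sorted(num for num, _, _ in entries)
    prefix = [0]
    for num in nums:
        prefix.append(prefix[-1] + num)
    ten7 = 10**7
    for num_obs, a, b in entries:
        # rightmost index with nums[i] * 1e7 <= num_obs * (1e7 + 1), exactly
        limit = num_obs * (ten7 + 1)
        lo, hi = 0, len(nums)
        while lo < hi:
            mid = (lo + hi) // 2
            if nums[mid] * ten7 <= limit:
                lo = mid + 1
            else:
                hi = mid
        cc = c0 - a - b
        table = [[a, r0 - a], [b, r1 - b], [cc, r2 - cc]]
        yield table, prefix[lo] / denom


def mann_whitney_exact_oracle(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties allowed).

    Counts assignments of the pooled values whose U is at least as extreme
    (in either tail) as the observed one; for the tie-free symmetric null
    this equals the doubled one-tail probability, capped at 1.
    """
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(a), len(b)
    m = n1 * n2

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    lo = min(u_obs, m - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = u_stat(ga, gb)
        if u <= lo or u >= m - lo:
            count += 1
        total += 1
    return count / total
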