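"""Independent brute-force oracles for the exact 2x2 statistics.

Everything here enumerates the hypergeometric support with exact integer
combinatorics (math.comb) — no shared code with the package's log-space
implementation.
"""

from math import comb

# same relative fuzz as the implementation's two-sided convention, applied in
# exact integer arithmetic: include x iff N(x) * 10^7 <= N(a) * (10^7 + 1)
_EPS_NUM = 10**7 + 1
_EPS_DEN = 10**7


def support_numerators(k: int, m1: int, n: int) -> tuple[list[int], list[int], int]:
    m2 = n - m1
    xs = list(range(max(0, k - m2), min(k, m1) + 1))
    nums = [comb(m1, x) * comb(m2, k - x) for x in xs]
    return xs, nums, comb(n, k)


def enum_p_greater(a: int, b: int, c: int, d: int) -> float:
    n, m1, k = a + b + c + d, a + b, a + c
    xs, nums, denom = support_numerators(k, m1, n)
    total = sum(num for x, num in zip(xs, nums) if x >= a)
    return total / denom


def enum_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    n, m1, k = a + b + c + d, a + b, a + c
    xs, nums, denom = support_numerators(k, m1, n)
    obs = nums[xs.index(a)]
    total = sum(num for num in nums if num * _EPS_DEN <= obs * _EPS_NUM)
    return min(total / denom, 1.0)
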