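"""Brute-force dynamic-programming alignment oracle for the tests.

Independent textbook implementation of semi-global alignment (end gaps on the
query's flanks are free, i.e. the reference may overhang without penalty)
with unit costs for substitutions and gap bases.  Quadratic and slow on
purpose; used only on short instances.
"""


def dp_mismatches(query: str, reference: str) -> int:
    m, n = len(query), len(reference)
    prev = [0] * (n + 1)  # free leading reference overhang
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qi = query[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j - 1] + (qi != reference[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)  # free trailing reference overhang
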