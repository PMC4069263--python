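"""Independent brute-force oracles shared across test modules."""

import math


def bh_stepup_oracle(p):
    """Literal step-up definition: q_i = min over p_j >= p_i of m p_j / r_j."""
    p = list(p)
    m = len(p)
    ranked = sorted(range(m), key=lambda i: p[i])
    rank = {i: r + 1 for r, i in enumerate(ranked)}
    out = []
    for i in range(m):
        candidates = [m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]]
        out.append(min(1.0, min(candidates)))
    return out


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of overlap counts."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(max(k, 0), min(K, n) + 1)) / total
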