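"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops / explicit summations,
deliberately avoiding the matrix-product and log-space code paths of the
package, so agreement between the two routes is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def pairwise_counts(values: np.ndarray, axis: str) -> dict[str, int]:
    """Pair counts by explicit loops over *ordered* pairs (doubled counts)."""
    v = np.asarray(values)
    if axis == "cpgs":
        v = v.T
    n = v.shape[0]
    m = cn = t = pooled_m = pooled_u = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for k in range(v.shape[1]):
                a, b = v[i, k], v[j, k]
                if a == MISSING or b == MISSING:
                    continue
                t += 1
                if a == 1 and b == 1:
                    m += 1
                if a == 0 and b == 0:
                    cn += 1
                # pooled composition: the second member's state, once per
                # covered position of the first (T A^T off-diagonal sums)
                if b == 1:
                    pooled_m += 1
                else:
                    pooled_u += 1
    return {"m": m, "n": cn, "t": t, "pooled_m": pooled_m, "pooled_u": pooled_u}


def binom_tail(observed: int, trials: int, e: float) -> float:
    """Exact one-sided tail by explicit pmf summation (log-gamma terms)."""

    def pmf(i: int) -> float:
        logc = (
            math.lgamma(trials + 1) - math.lgamma(i + 1) - math.lgamma(trials - i + 1)
        )
        return math.exp(logc + i * math.log(e) + (trials - i) * math.log(1 - e))

    if observed < trials * e:
        return sum(pmf(i) for i in range(0, observed + 1))
    return sum(pmf(i) for i in range(observed, trials + 1))


def score(values: np.ndarray) -> dict[str, float]:
    """Full oracle scoring pipeline (raw, expected, normalized, p-values)."""
    out: dict[str, float] = {}
    for axis, tag in (("reads", "r"), ("cpgs", "c")):
        c = pairwise_counts(values, axis)
        if c["t"] == 0:
            out.update(
                {
                    f"raw_{tag}": float("nan"),
                    f"nrm_{tag}": float("nan"),
                    f"p_{tag}": float("nan"),
                }
            )
            continue
        raw = (c["m"] + c["n"]) / c["t"]
        p = c["pooled_m"] / (c["pooled_m"] + c["pooled_u"])
        e = p * p + (1 - p) * (1 - p)
        out[f"raw_{tag}"] = raw
        out[f"nrm_{tag}"] = raw - e
        out[f"p_{tag}"] = 1.0 if not (0 < e < 1) else binom_tail(c["m"] + c["n"], c["t"], e)
    return out


def qfdrp(values: np.ndarray) -> float:
    """Pooled discordance over unordered read pairs, by loops."""
    v = np.asarray(values)
    disc = shared = 0
    for i in range(v.shape[0]):
        for j in range(i + 1, v.shape[0]):
            for k in range(v.shape[1]):
                if v[i, k] == MISSING or v[j, k] == MISSING:
                    continue
                shared += 1
                if v[i, k] != v[j, k]:
                    disc += 1
    return disc / shared if shared else float("nan")


def random_ternary(rng: np.random.Generator, max_r=15, max_c=10, max_missing=0.5):
    r = int(rng.integers(2, max_r + 1))
    c = int(rng.integers(2, max_c + 1))
    p = float(rng.uniform(0.05, 0.95))
    miss = float(rng.uniform(0.0, max_missing))
    v = (rng.random((r, c)) < p).astype(np.int8)
    v[rng.random((r, c)) < miss] = MISSING
    return v
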