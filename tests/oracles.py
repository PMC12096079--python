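"""Independent reference implementations used only to check the package.

These deliberately avoid the package's code paths (and numpy where easy):
the peak-caller oracle is explicit loops with ``statistics`` arithmetic, and
the Mann-Whitney oracle enumerates the exact permutation distribution of U.
"""

from __future__ import annotations

import itertools
import statistics


def brute_force_windows(length, window=50, step=25, min_window=10):
    """All sliding windows, by explicit enumeration."""
    out = []
    for start in range(0, length, step):
        end = min(start + window, length)
        if end - start >= min_window:
            out.append((start, end))
        if end == length:
            break
    return out


def brute_force_call_peaks(
    ip_depth,
    input_depth,
    window=50,
    step=25,
    min_cov=10.0,
    min_pom=3.0,
    min_poi=3.0,
):
    """Reference peak caller: returns [(start, end, poi), ...].

    Explicit loops over all windows; POM = window mean / transcript median
    (zeros included, undefined when the median is 0); candidates must pass
    the coverage/POM filter in IP and not in input; POI = POM_ip / POM_in
    on the raw input POM; POI > min_poi retained; overlapping/adjacent
    retained windows merged with max-POI scoring.
    """
    # plain Python numbers: statistics.mean coerces its result back to the
    # element type, which would truncate numpy integer input
    ip_depth = [float(v) for v in ip_depth]
    input_depth = [float(v) for v in input_depth]
    length = len(ip_depth)
    if length < step:
        return []

    def pom_of(depth, start, end):
        med = statistics.median(depth)
        if med == 0:
            return None, statistics.mean(depth[start:end])
        mean = statistics.mean(depth[start:end])
        return mean / med, mean

    retained = []
    for start, end in brute_force_windows(length, window, step):
        pom_ip, mean_ip = pom_of(ip_depth, start, end)
        if pom_ip is None or mean_ip < min_cov or pom_ip < min_pom:
            continue
        pom_in, mean_in = pom_of(input_depth, start, end)
        if pom_in is not None and mean_in >= min_cov and pom_in >= min_pom:
            continue  # shared region
        if pom_in is None or pom_in == 0:
            continue
        poi = pom_ip / pom_in
        if poi > min_poi:
            retained.append((start, end, poi))

    peaks = []
    for start, end, poi in sorted(retained):
        if peaks and start <= peaks[-1][1]:
            prev = peaks.pop()
            peaks.append((prev[0], max(prev[1], end), max(prev[2], poi)))
        else:
            peaks.append((start, end, poi))
    return peaks


def exact_mann_whitney_p(x, y):
    """Two-sided exact Mann-Whitney p-value by full enumeration.

    Valid for tie-free samples; enumerates all C(n1+n2, n1) group
    assignments of the pooled values and uses the 2*min(tail) convention.
    """
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_stat(xs, ys))
    n_total = len(us)
    cdf = sum(1 for u in us if u <= u_obs) / n_total
    sf = sum(1 for u in us if u >= u_obs) / n_total
    return min(1.0, 2.0 * min(cdf, sf))


def binomial_tail_fp_expectation(depths, error_rate, min_frac=0.5, min_depth=20):
    """Closed-form expected persistent-call count at background A sites.

    For each site with depth n >= min_depth the false-positive probability
    is P[Bin(n, error_rate) >= ceil(min_frac * n)]; depths below min_depth
    contribute 0. Returns (expected count, variance) of the Poisson-binomial
    total.
    """
    import math

    expected = 0.0
    variance = 0.0
    for n in depths:
        if n < min_depth or n == 0:
            continue
        k_min = math.ceil(min_frac * n)
        p = sum(
            math.comb(n, k) * error_rate**k * (1 - error_rate) ** (n - k)
            for k in range(k_min, n + 1)
        )
        expected += p
        variance += p * (1 - p)
    return expected, variance
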