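"""Independent reference implementations used only as test oracles.

Deliberately written in a different style from the package (ordinal-day
integers, direct scans, bisection instead of closed-form quantiles) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

from scipy.special import ndtr


# -- direct-scan phenotyping oracle ----------------------------------------


def oracle_episodes(prescriptions, gap_days=98):
    """Episodes as (drug, start_ord, end_ord, n) tuples via a direct scan.

    ``prescriptions`` is a list of (drug_id, date) pairs.
    """
    by_drug = {}
    for drug, d in prescriptions:
        by_drug.setdefault(drug, []).append(d.toordinal())
    episodes = []
    for drug, days in by_drug.items():
        days = sorted(days)
        i = 0
        while i < len(days):
            j = i
            while j + 1 < len(days) and days[j + 1] - days[j] <= gap_days:
                j += 1
            episodes.append((drug, days[i], days[j], j - i + 1))
            i = j + 1
    episodes.sort(key=lambda e: (e[1], e[2], e[0]))
    return episodes


def oracle_switch_count(prescriptions, gap_days=98, min_days=42, overlap_days=30):
    """Number of switches by scanning adjacent qualifying-episode pairs."""
    eps = [e for e in oracle_episodes(prescriptions, gap_days) if e[2] - e[1] >= min_days]
    count = 0
    for k in range(len(eps) - 1):
        a, b = eps[k], eps[k + 1]
        if a[0] == b[0]:
            continue
        if b[1] - a[2] > gap_days:
            continue
        overlap = min(a[2], b[2]) - max(a[1], b[1])
        if overlap > overlap_days:
            continue
        count += 1
    return count


def oracle_is_trd(prescriptions, gap_days=98, min_days=42, overlap_days=30):
    """TRD label for a treated MDD case: at least two switches."""
    return oracle_switch_count(prescriptions, gap_days, min_days, overlap_days) >= 2


# -- numerical liability-scale oracle --------------------------------------


def _oracle_quantile(p):
    """x with Phi(x) = p by bisection on the normal CDF."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ndtr(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _oracle_density(x, h=1e-5):
    """phi(x) as a central difference of the normal CDF."""
    return (ndtr(x + h) - ndtr(x - h)) / (2 * h)


def oracle_h2_liability(h2_obs, k, p):
    t = _oracle_quantile(1.0 - k)
    z = _oracle_density(t)
    return h2_obs * k * k * (1 - k) ** 2 / (z * z * p * (1 - p))


def oracle_r2_liability(r2_obs, k, p):
    """Lee (2012) ascertainment-corrected liability R2 with numerically
    derived threshold and density."""
    t = _oracle_quantile(1.0 - k)
    z = _oracle_density(t)
    m = z / k
    c = k * (1 - k) / (z * z) * k * (1 - k) / (p * (1 - p))
    d = m * (p - k) / (1 - k)
    return c * r2_obs / (1 + c * d * (d - t) * r2_obs)


def oracle_two_sided_p(z):
    """2(1 - Phi(|z|)) via the CDF (adequate for moderate z in tests)."""
    return 2.0 * (1.0 - ndtr(abs(z)))


def oracle_prevalence_percent(n_case, n_total):
    return round(100.0 * n_case / n_total + 1e-12, 2)


def oracle_log_or(a, b, c, d):
    return math.log((a * d) / (b * c))
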