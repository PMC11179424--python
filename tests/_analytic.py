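"""Independent analytic oracles for the expansion/measurement model.

Everything here is computed directly from scipy/numpy closed forms in the
infinite-allele limit — smoothed Poisson gain distributions, threshold
truncation, through-origin least squares — without touching the package's
own code paths, so it can serve as the expected-value oracle for the
Monte-Carlo pipeline.
"""

import numpy as np
from scipy import stats


def smoothed_masses(lam, stutter_ratio, stutter_orders, jmax=None):
    """Mass over net measured offset d = Poisson gains minus stutter offset."""
    if jmax is None:
        jmax = int(max(20, lam + 10 * np.sqrt(max(lam, 1.0))))
    j = np.arange(0, jmax + 1)
    p = stats.poisson.pmf(j, lam) if lam > 0 else (j == 0).astype(float)
    d = np.arange(-stutter_orders, jmax + 1)
    m = np.zeros(d.size)
    for k in range(stutter_orders + 1):
        m[(j - k) + stutter_orders] += p * stutter_ratio**k
    return d, m / m.sum()


def thresholded_index(lam, stutter_ratio, stutter_orders, threshold):
    """Expected instability index (offset units) after threshold filtering."""
    d, m = smoothed_masses(lam, stutter_ratio, stutter_orders)
    keep = m >= threshold * m.max()
    mk = m[keep] / m[keep].sum()
    return float(np.sum(mk * d[keep]))


def expected_modal_offset(lam, stutter_ratio, stutter_orders):
    """Mode of the smoothed gain distribution (offset from baseline mode)."""
    d, m = smoothed_masses(lam, stutter_ratio, stutter_orders)
    return int(d[np.argmax(m)])


def expected_index_slope(gain_rate, times_days, stutter_ratio, stutter_orders,
                         threshold, per=1.0):
    """Through-origin OLS slope of the expected baseline-delta index.

    ``per`` rescales the time axis (7.0 reports units/week).
    """
    t = np.asarray(times_days, dtype=float) / per
    y = np.array(
        [
            thresholded_index(gain_rate * td, stutter_ratio, stutter_orders, threshold)
            - thresholded_index(0.0, stutter_ratio, stutter_orders, threshold)
            for td in times_days
        ]
    )
    return float((t @ y) / (t @ t))


def expected_percent_slowing(multiplier, gain_rate, times_days, stutter_ratio,
                             stutter_orders, threshold):
    """Expected measured index slowing of a knockdown arm vs control."""
    s_ctrl = expected_index_slope(gain_rate, times_days, stutter_ratio,
                                  stutter_orders, threshold)
    s_arm = expected_index_slope(multiplier * gain_rate, times_days, stutter_ratio,
                                 stutter_orders, threshold)
    return 100.0 * (1.0 - s_arm / s_ctrl)
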