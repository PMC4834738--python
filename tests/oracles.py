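"""Independent brute-force re-derivations used as test oracles.

Deliberately written without reference to the package internals: plain
loops, dictionaries, and separately-coded least-squares formulas, so that a
bug in the implementation cannot hide in a shared helper.
"""

import numpy as np

from weightzone.adherence import Flag


def brute_clean(records, threshold=0.05):
    """First-of-day + sequential strict >threshold filter, by brute force.

    ``records`` are (timestamp, weight_kg) pairs.  Returns the list of
    (date, weight) ultimately retained.
    """
    first_of_day = {}
    for ts, w in sorted(records, key=lambda r: r[0]):
        d = ts.date()
        if d not in first_of_day:
            first_of_day[d] = w
    kept = []
    ref = None
    for d in sorted(first_of_day):
        w = first_of_day[d]
        if ref is None or abs(w - ref) / ref <= threshold:
            kept.append((d, w))
            ref = w
    return kept


def ols_slope_se(x, y):
    """Least-squares slope and standard error via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    if n > 2:
        se = np.sqrt((resid @ resid) / (n - 2) / (sxx - sx * sx / n))
    else:
        se = 0.0
    return float(slope), float(se)


def oracle_flag(weight_by_day, day, predicted, lower, upper,
                slope_window=7, min_slope_points=3, plateau_z=1.645,
                upper_edge_fraction=0.2):
    """Re-derive the color flag for one day from first principles."""
    w = weight_by_day.get(day)
    if w is None:
        return Flag.NO_DATA
    lo, up = lower[day], upper[day]
    pts = [(d, wt) for d, wt in weight_by_day.items()
           if day - slope_window + 1 <= d <= day]
    pred_slope = predicted[max(day, 1)] - predicted[max(day, 1) - 1]
    slope = se = None
    if len(pts) >= min_slope_points:
        slope, se = ols_slope_se([p[0] for p in pts], [p[1] for p in pts])
    if lo <= w <= up:
        if w >= up - upper_edge_fraction * (up - lo):
            return Flag.GREEN_YELLOW
        if slope is not None and pred_slope < 0 and slope - plateau_z * se >= -1e-9:
            return Flag.GREEN_YELLOW
        return Flag.GREEN
    if w > up:
        if slope is not None and slope <= pred_slope:
            return Flag.RED_GREEN
        return Flag.RED
    return Flag.RED
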