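"""Independent direct-summation oracles for the agreement statistics.

Pure-Python sums only — deliberately no numpy/scipy vector paths — so the
main implementation is checked against an arithmetically independent route.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def pearson_r(xs, ys):
    n = len(xs)
    mx, my = _mean(xs), _mean(ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def lins_ccc(xs, ys):
    n = len(xs)
    mx, my = _mean(xs), _mean(ys)
    sx2 = sum((x - mx) ** 2 for x in xs) / n
    sy2 = sum((y - my) ** 2 for y in ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def ols(xs, ys):
    """(slope, intercept) of ys regressed on xs via the normal equations."""
    n = len(xs)
    mx, my = _mean(xs), _mean(ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    slope = sxy / sxx
    return slope, my - slope * mx


def bland_altman(method, reference, multiplier=2.0):
    diffs = [m - r for m, r in zip(method, reference)]
    n = len(diffs)
    bias = _mean(diffs)
    sd = math.sqrt(sum((d - bias) ** 2 for d in diffs) / (n - 1))
    return bias, sd, bias - multiplier * sd, bias + multiplier * sd


def proportional_bias_slope(method, reference):
    diffs = [m - r for m, r in zip(method, reference)]
    avgs = [(m + r) / 2 for m, r in zip(method, reference)]
    return ols(avgs, diffs)


def paired_t(method, reference):
    diffs = [m - r for m, r in zip(method, reference)]
    n = len(diffs)
    md = _mean(diffs)
    sd = math.sqrt(sum((d - md) ** 2 for d in diffs) / (n - 1))
    return md / (sd / math.sqrt(n))


def tbw_kg(dose_g, concentration_pct, ap_post, ap_pre):
    """Step-by-step evaluation of the plateau dilution formula."""
    step1 = dose_g * (concentration_pct / 20.0)
    step2 = step1 * 18.02
    step3 = step2 / (ap_post - ap_pre)
    step4 = step3 * 1e-3
    return step4 / 1.04


def fuller_fm(bv_L, tbw_L, bmc_g, weight_kg):
    return 2.7474 * bv_L - 0.7145 * tbw_L + 1.4599 * (bmc_g / 1000.0) - 2.0503 * weight_kg


def best_volume_pair(readings, threshold=0.150):
    """Brute-force enumeration of agreeing pairs; earliest-reading tie-break."""
    best = None
    n = len(readings)
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(readings[i] - readings[j])
            if d <= threshold:
                key = (d, i, j)
                if best is None or key < best[0]:
                    best = (key, (readings[i] + readings[j]) / 2.0)
    return None if best is None else best[1]
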