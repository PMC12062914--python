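"""Independent direct-summation oracle for registry statistics.

Pure-Python reimplementation of every statistic with explicit loops and
``math`` only — no numpy, no imports from the package's rate engine — used
to cross-check the engine on random instances.
"""

import math

NAN = float("nan")


def age_specific(counts, person_years, scale):
    out = []
    for c, p in zip(counts, person_years):
        out.append(c / p * scale if p > 0 else NAN)
    return out


def crude(counts_total, person_years, scale):
    total_py = 0.0
    for p in person_years:
        total_py += p
    return counts_total / total_py * scale


def asr(rates, weights, indices=None):
    if indices is None:
        indices = range(len(rates))
    num = den = 0.0
    any_ok = False
    for i in indices:
        if math.isnan(rates[i]):
            continue
        any_ok = True
        num += weights[i] * rates[i]
        den += weights[i]
    return num / den if any_ok else NAN


def cumulative_rate(rates, widths, indices, scale):
    acc = 0.0
    for i in indices:
        if not math.isnan(rates[i]):
            acc += widths[i] * rates[i] / scale
    return 100.0 * acc


def cumulative_risk(cum_rate_percent):
    return 100.0 * (1.0 - math.exp(-cum_rate_percent / 100.0))


def person_risk(cum_risk_percent):
    if cum_risk_percent == 0:
        return None
    return max(1, int(round(100.0 / cum_risk_percent)))


def quality_percentages(mv, dco, total):
    if total == 0:
        return (NAN, NAN)
    return (100.0 * mv / total, 100.0 * dco / total)


def mi_ratio(mortality, incidence):
    return mortality / incidence if incidence > 0 else NAN


def age_percent(counts, total):
    if total == 0:
        return [NAN] * len(counts)
    return [100.0 * c / total for c in counts]
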