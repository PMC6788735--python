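"""Independent brute-force oracles for the variability metrics.

Deliberately written in the plainest possible style (pure-Python loops,
the ``statistics`` module, dictionary lookups on raw timestamps) so that
they share no code path with the vectorized implementations they check.
"""
import statistics
from datetime import timedelta


def mage_oracle(values, k_multiplier):
    """Baghurst MAGE by literal enumeration.

    Collapse plateaus, list every interior point that is a strict local
    extremum, then repeatedly find the smallest adjacent amplitude (ties:
    earliest) and, while it fails the k*SD gate, delete that pair of
    turning points.  Returns the mean retained amplitude, or None.
    """
    vals = []
    for v in values:
        v = float(v)
        if not vals or v != vals[-1]:
            vals.append(v)
    turning = []
    for i in range(1, len(vals) - 1):
        rising_in = vals[i] > vals[i - 1]
        rising_out = vals[i + 1] > vals[i]
        if rising_in != rising_out:
            turning.append(vals[i])
    if len(list(values)) < 2:
        return None
    sd = statistics.stdev(float(v) for v in values)
    if sd == 0:
        return None
    gate = k_multiplier * sd
    while len(turning) >= 2:
        best_j, best_amp = None, None
        for j in range(len(turning) - 1):
            amp = abs(turning[j + 1] - turning[j])
            if best_amp is None or amp < best_amp:
                best_j, best_amp = j, amp
        if best_amp > gate:
            break
        del turning[best_j + 1]
        del turning[best_j]
    if len(turning) < 2:
        return None
    amps = [abs(turning[j + 1] - turning[j]) for j in range(len(turning) - 1)]
    return sum(amps) / len(amps)


def conga_oracle(trace, n_hours):
    """SD of g(t) - g(t - n hours), matching raw timestamps exactly."""
    lookup = {ts: g for ts, g in zip(trace.times, trace.glucose)}
    lag = timedelta(hours=n_hours)
    diffs = [g - lookup[ts - lag] for ts, g in lookup.items() if ts - lag in lookup]
    if len(diffs) < 2:
        return None
    return statistics.stdev(diffs)


def modd_oracle(trace):
    """Mean |g(t) - g(t - 24 h)|, matching raw timestamps exactly."""
    lookup = {ts: g for ts, g in zip(trace.times, trace.glucose)}
    lag = timedelta(hours=24)
    diffs = [abs(g - lookup[ts - lag]) for ts, g in lookup.items() if ts - lag in lookup]
    if not diffs:
        return None
    return sum(diffs) / len(diffs)


def excursion_count_oracle(values, interval, threshold, min_duration, side):
    """Count maximal runs beyond a threshold meeting the duration gate."""
    count = 0
    run = 0
    for v in list(values) + [None]:
        beyond = v is not None and (v >= threshold if side == "over" else v <= threshold)
        if beyond:
            run += 1
        else:
            if run and run * interval >= min_duration:
                count += 1
            run = 0
    return count
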