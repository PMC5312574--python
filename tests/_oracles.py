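"""Independent reference implementations used to cross-check the package.

These are deliberately written in a different style from the library code
(plain lists, explicit scans, no shared helpers) so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def replay_reward_times(stream, spec, seed=None):
    """Single-pass replay of a raw input stream; returns the reward times.

    Mirrors the engine's contract from the outside: licks on the active
    spout count unless they fall in the half-open post-reward timeout
    window; FR uses a fixed requirement, PR an arithmetic progression, and
    VR one uniform draw on {1, ..., 2*mean-1} at start and after each
    reward (``vr_values``, when set, is cycled instead). FR/VR sessions
    cover [0, session_s); PR sessions end pr_idle_stop_s after the last
    active lick of the whole stream.
    """
    t0 = stream[0].time
    lick_ts = [e.time - t0 for e in stream[1:] if e.kind.value == "lick_active"]
    family = spec.family.value
    if family == "PR":
        cutoff = (lick_ts[-1] if lick_ts else 0.0) + spec.pr_idle_stop_s
        usable = [t for t in lick_ts if t <= cutoff]
    else:
        usable = [t for t in lick_ts if t < spec.session_s]

    if family == "VR":
        if spec.vr_values is not None:
            cycle = itertools.cycle(spec.vr_values)
            draw = lambda: next(cycle)  # noqa: E731
        else:
            g = np.random.default_rng(seed)
            draw = lambda: int(g.integers(1, 2 * spec.ratio))  # noqa: E731

    def requirement(n_rewards_so_far):
        if family == "FR":
            return spec.ratio
        if family == "PR":
            return spec.ratio + n_rewards_so_far * spec.pr_step
        return draw()

    req = requirement(0)
    count = 0
    rewards = []
    blocked_until = None
    for t in usable:
        if blocked_until is not None and t < blocked_until:
            continue
        count += 1
        if count == req:
            rewards.append(t)
            count = 0
            blocked_until = t + spec.timeout_s if spec.timeout_s > 0 else None
            req = requirement(len(rewards))
    return rewards


def naive_segment(times, threshold):
    """Quadratic-flavoured reference segmentation via label propagation.

    Builds connected components of the "closer than threshold" relation on
    consecutive licks by repeatedly sweeping the label array, then drops
    components with fewer than two licks.
    """
    times = [float(t) for t in times]
    n = len(times)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(1, n):
            if times[i] - times[i - 1] < threshold:
                lab = min(labels[i], labels[i - 1])
                if labels[i] != lab:
                    labels[i] = lab
                    changed = True
                if labels[i - 1] != lab:
                    labels[i - 1] = lab
                    changed = True
    groups: dict[int, list[float]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(times[i])
    return [g for _, g in sorted(groups.items()) if len(g) >= 2]


def running_counts(event_times):
    """Step-function (time, cumulative count) pairs built by explicit counting."""
    out = []
    c = 0
    for t in event_times:
        c = c + 1
        out.append((t, c))
    return out


def pooled_t_test(a, b):
    """Closed-form two-sample pooled-variance Student's t (two-sided p)."""
    from scipy.stats import t as tdist

    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = (sp2 * (1.0 / na + 1.0 / nb)) ** 0.5
    t_stat = (ma - mb) / se
    p = 2.0 * tdist.sf(abs(t_stat), df)
    return t_stat, p
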