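"""Independent reference implementations used only by the test suite.

These deliberately use naive O(n*w) loops and explicit per-contact
sampling so that they share no code path with the package internals
they check.
"""

from __future__ import annotations

import numpy as np


def brute_rolling_max_7(x: np.ndarray) -> np.ndarray:
    """Centered 7-day rolling maximum with edge-clipped windows."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        out[i] = max(x[max(i - 3, 0): i + 4])
    return out


def brute_peak_prominences(x: np.ndarray) -> list[tuple[int, float]]:
    """Textbook topographic prominence of every local maximum.

    A local maximum is a maximal run of equal samples with strictly
    lower neighbours on both sides (interior only; series edges are
    never peaks) and is reported at its leftmost index.  From a peak,
    walk outward on each side until a strictly higher sample or the
    series edge; the peak's base on that side is the minimum seen.
    Prominence is peak height minus the larger base.
    """
    n = len(x)
    res = []
    a = 1
    while a < n - 1:
        b = a
        while b + 1 < n and x[b + 1] == x[a]:
            b += 1
        if x[a - 1] < x[a] and b < n - 1 and x[b + 1] < x[a]:
            left_min = x[a]
            j = a - 1
            while j >= 0 and x[j] <= x[a]:
                left_min = min(left_min, x[j])
                j -= 1
            right_min = x[a]
            j = b + 1
            while j < n and x[j] <= x[a]:
                right_min = min(right_min, x[j])
                j += 1
            res.append((a, x[a] - max(left_min, right_min)))
        a = b + 1
    return res


def brute_count_waves(x: np.ndarray, prominence: float) -> int:
    return sum(1 for _, p in brute_peak_prominences(x) if p >= prominence)


def naive_contact_epidemic(
    household_id: np.ndarray,
    community: np.ndarray,
    w_household: float,
    w_community: float,
    degree: int,
    dwell_mean: float,
    seeds: np.ndarray,
    horizon: int,
    rng: np.random.Generator,
) -> float:
    """Per-contact epidemic with a fixed 2-day latency on households +
    one ambient community layer.

    Mirrors the engine's documented contact law with explicit loops:
    each day, against the morning snapshot, complete mixing within
    households plus ``2 * degree`` uniform partner draws (with
    replacement, self-draws allowed and inert) from the community - the
    engine samples the ambient layer once per phase.  New infections
    spend exactly two days latent, then are infectious for a geometric
    number of days.  Returns the attack rate.
    """
    n = len(household_id)
    S_, E_, I_, R_ = 0, 1, 2, 3
    state = np.zeros(n, dtype=int)
    timer = np.zeros(n, dtype=int)
    state[seeds] = E_
    timer[seeds] = 2

    hh_members: dict[int, list[int]] = {}
    for a, h in enumerate(household_id):
        hh_members.setdefault(int(h), []).append(a)
    comm_members: dict[int, list[int]] = {}
    for a, c in enumerate(community):
        comm_members.setdefault(int(c), []).append(a)

    for _ in range(horizon):
        infectious = state == I_
        new = []
        for a in range(n):
            if state[a] != S_:
                continue
            infected = False
            for b in hh_members[int(household_id[a])]:
                if b != a and infectious[b] and rng.random() < w_household:
                    infected = True
            members = comm_members[int(community[a])]
            for _k in range(2 * degree):
                b = members[rng.integers(len(members))]
                if b != a and infectious[b] and rng.random() < w_community:
                    infected = True
            if infected:
                new.append(a)
        timer[(state == E_) | infectious] -= 1
        state[infectious & (timer <= 0)] = R_
        latent_done = (state == E_) & (timer <= 0)
        state[latent_done] = I_
        timer[latent_done] = rng.geometric(1.0 / dwell_mean, int(latent_done.sum()))
        for a in new:
            state[a] = E_
            timer[a] = 2
    return float((state != S_).sum()) / n
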