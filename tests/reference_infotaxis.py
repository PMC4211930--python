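"""Independent brute-force reference for the infotaxis agent.

Deliberately naive: dictionaries, explicit Python loops, the unscaled Bessel
function, and explicit construction of both posterior branches of the
expected-gain formula.  Used only as an oracle in tests.
"""

import math

import numpy as np
from scipy.special import k0

ACTIONS = ("forward", "backward", "left", "right", "stay")
STEPS = {"forward": (0, 1), "backward": (0, -1), "left": (-1, 0),
         "right": (1, 0), "stay": (0, 0)}


def bf_rate(pos, cell, params):
    lam = math.sqrt(params.patch_lifetime * params.diffusivity /
                    (1.0 + params.wind_speed ** 2 * params.patch_lifetime /
                     (4.0 * params.diffusivity)))
    r = math.hypot(pos[0] - cell[0], pos[1] - cell[1])
    r = max(r, params.agent_size)
    return (params.emission_rate / math.log(lam / params.agent_size)
            * math.exp(-(pos[1] - cell[1]) * params.wind_speed /
                       (2.0 * params.diffusivity))
            * k0(r / lam))


def bf_cell_of(pos, cells, spacing):
    for c in cells:
        if (abs(pos[0] - c[0]) <= spacing / 2 + 1e-9
                and abs(pos[1] - c[1]) <= spacing / 2 + 1e-9):
            return c
    return None


def bf_update(prob, pos, dt, k, params, cells, spacing):
    new = {}
    for c in cells:
        mu = bf_rate(pos, c, params) * dt
        like = mu ** k * math.exp(-mu) / math.factorial(k)
        new[c] = prob[c] * like
    here = bf_cell_of(pos, cells, spacing)
    if here is not None:
        new[here] = 0.0
    total = sum(new.values())
    if total <= 0:
        raise ValueError("all-zero posterior")
    return {c: w / total for c, w in new.items()}


def bf_entropy(prob):
    s = 0.0
    for w in prob.values():
        if w > 0:
            s -= w * math.log2(w)
    return s


def bf_gain(prob, action, pos, dt, params, cells, spacing):
    dx, dy = STEPS[action]
    landing = (pos[0] + dx * spacing, pos[1] + dy * spacing)
    here = bf_cell_of(landing, cells, spacing)
    if here is None:
        raise IndexError("landing outside grid")
    s0 = bf_entropy(prob)
    p_found = prob[here]
    rho0 = 0.0
    for c in cells:
        mu = bf_rate(landing, c, params) * dt
        rho0 += prob[c] * math.exp(-mu)
    gain = 0.0
    for k, rho in ((0, rho0), (1, 1.0 - rho0)):
        if rho <= 0:
            continue
        try:
            sk = bf_entropy(bf_update(prob, landing, dt, k, params, cells,
                                      spacing))
        except ValueError:
            sk = 0.0
        gain += rho * (s0 - sk)
    return p_found * s0 + (1.0 - p_found) * gain


def bf_choose(prob, pos, params, cells, spacing, rng, action_dt):
    gains = []
    admissible = []
    for a in ACTIONS:
        dx, dy = STEPS[a]
        landing = (pos[0] + dx * spacing, pos[1] + dy * spacing)
        if bf_cell_of(landing, cells, spacing) is None:
            continue
        admissible.append(a)
        gains.append(bf_gain(prob, a, pos, action_dt(a), params, cells,
                             spacing))
    best = max(gains)
    cands = [a for a, g in zip(admissible, gains) if best - g <= 1e-12]
    return cands[int(rng.integers(len(cands)))]
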