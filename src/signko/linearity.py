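"""Local-linearity motif tests and sign-permutation null model.

Three motif-level properties jointly characterize every way a functional
network can contradict sign-linearity within at most two knocked-out genes
and two affected genes:

* **LL-1** — for an ordered pair (a, b) with an (a, b) edge and a shared
  target t: if a and b affect t in the same way, a's effect on b should be
  down-regulation (sign +1), if oppositely, up-regulation.  Formally
  s(a,b) = s(a,t) * s(b,t).
* **LL-2** — two knockouts a, b with common targets t1, t2 must act
  equivalently on both or exactly oppositely on both:
  (s(a,t1) = s(b,t1)) iff (s(a,t2) = s(b,t2)).
* **LL-3** — reciprocal effects are symmetric: s(a,b) = s(b,a).

Prevalence of each property is compared against a null in which edge signs
are permuted uniformly across the fixed topology (preserving the sign
multiset), with a z-score and an add-one two-sided empirical p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .netio import FunctionalNetwork

__all__ = [
    "LLReport",
    "ll1_instances",
    "ll2_instances",
    "ll3_instances",
    "randomize_signs",
    "ll_report",
    "PROPERTIES",
]

PROPERTIES = ("LL1", "LL2", "LL3")


@dataclass(frozen=True)
class LLReport:
    property: str
    n_instances: int
    n_satisfied: int
    prevalence: float  # NaN when no instances
    null_prevalences: tuple
    z_score: float  # NaN when undefined (sd 0 or no instances)
    empirical_p: float


def ll1_instances(net: FunctionalNetwork):
    """Ordered triples (a, b, t) with edges (a,t), (b,t), (a,b); t not in {a,b}.

    Satisfied iff s(a,b) = s(a,t)*s(b,t).  Antiparallel (a,b)/(b,a) edges
    yield separate instances.
    """
    signs = net.edge_signs
    targets_of: dict[str, dict[str, int]] = {}
    for (u, t), s in signs.items():
        targets_of.setdefault(u, {})[t] = s
    out = []
    for (a, b), s_ab in signs.items():
        ta = targets_of.get(a, {})
        tb = targets_of.get(b, {})
        for t, s_at in ta.items():
            if t == b or t == a:
                continue
            s_bt = tb.get(t)
            if s_bt is None:
                continue
            out.append((a, b, t, s_ab == s_at * s_bt))
    return out


def ll2_instances(net: FunctionalNetwork):
    """Unordered pairs {a,b} x unordered common-target pairs {t1,t2}.

    Satisfied iff agreement on t1 and on t2 coincide (equivalent or exact
    opposite behavior).
    """
    signs = net.edge_signs
    targets_of: dict[str, dict[str, int]] = {}
    for (u, t), s in signs.items():
        targets_of.setdefault(u, {})[t] = s
    out = []
    kos = sorted(targets_of)
    for a, b in combinations(kos, 2):
        ta, tb = targets_of[a], targets_of[b]
        common = sorted(t for t in ta if t in tb and t not in (a, b))
        for t1, t2 in combinations(common, 2):
            agree1 = ta[t1] == tb[t1]
            agree2 = ta[t2] == tb[t2]
            out.append((a, b, t1, t2, agree1 == agree2))
    return out


def ll3_instances(net: FunctionalNetwork):
    """Unordered pairs {a,b} with both (a,b) and (b,a) edges present.

    Satisfied iff the reciprocal signs are equal.
    """
    signs = net.edge_signs
    out = []
    for (a, b), s_ab in signs.items():
        if a < b and (b, a) in signs:
            out.append((a, b, s_ab == signs[(b, a)]))
    return out


def randomize_signs(net: FunctionalNetwork, seed: int) -> FunctionalNetwork:
    """Permute edge signs uniformly at random over the fixed topology.

    The sign multiset (hence the '+' frequency q) is exactly preserved.
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(net.edge_signs)
    signs = np.array([net.edge_signs[p] for p in pairs])
    perm = rng.permutation(len(signs))
    return FunctionalNetwork(
        (u, v, int(signs[perm[i]])) for i, (u, v) in enumerate(pairs)
    )


_INSTANCE_FN = {
    "LL1": ll1_instances,
    "LL2": ll2_instances,
    "LL3": ll3_instances,
}


def _counts(net: FunctionalNetwork, prop: str) -> tuple[int, int]:
    inst = _INSTANCE_FN[prop](net)
    return len(inst), sum(1 for rec in inst if rec[-1])


def ll_report(
    net: FunctionalNetwork,
    prop: str,
    n_rand: int = 100,
    seed: int = 0,
) -> LLReport:
    """Prevalence of one LL property vs. the sign-permutation null.

    Instance counts are topology-determined and identical across the null
    networks; only satisfaction varies.  z = (obs - mean_null) / sd_null;
    empirical p is two-sided with add-one correction (r+1)/(n_rand+1).
    """
    prop = prop.upper()
    if prop not in _INSTANCE_FN:
        raise ValueError(f"unknown property {prop!r}")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    n_inst, n_sat = _counts(net, prop)
    if n_inst == 0:
        return LLReport(prop, 0, 0, math.nan, (), math.nan, math.nan)
    prevalence = n_sat / n_inst
    ss = np.random.SeedSequence(seed)
    null = []
    for child in ss.spawn(n_rand):
        rnet = randomize_signs(net, int(child.generate_state(1)[0] % (2**31)))
        ni, nsat = _counts(rnet, prop)
        null.append(nsat / ni)
    null_arr = np.asarray(null)
    sd = float(null_arr.std(ddof=1)) if n_rand > 1 else 0.0
    if sd > 0:
        z = (prevalence - float(null_arr.mean())) / sd
    else:
        z = math.nan
    r_hi = int(np.sum(null_arr >= prevalence))
    r_lo = int(np.sum(null_arr <= prevalence))
    p = min(1.0, 2.0 * (min(r_hi, r_lo) + 1) / (n_rand + 1))
    return LLReport(prop, n_inst, n_sat, prevalence, tuple(null), z, p)
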