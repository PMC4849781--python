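"""Molecule-level stochastic oracle for label propagation.

Independent of the ODE engine: metabolite pools are explicit populations
of molecules carrying ¹³C bitmasks; reaction events are drawn by tau-leap
from the deterministic rate laws, consume individual substrate molecules
chosen uniformly at random, and route their carbons through the
atom-transition map.  Symmetric species enter/leave in a random
orientation.  Restricted to single-compartment networks with ncell = 1 and
unit volume (all shipped toys).
"""

from __future__ import annotations

import numpy as np

from tracekin.experiments import Condition
from tracekin.kinetics import FluxEvaluator
from tracekin.labeling import _reverse_bits_perm


def mc_simulate(model, condition: Condition, t_end: float, *,
                n_per_mM: float = 1e5, dt: float = 0.02, seed: int = 0):
    """Return {metabolite: mask-count array} at t_end (labelable pools)."""
    net = condition.apply(model.network)
    assert len(net.compartments) == 1 and net.compartments[0].volume == 1.0
    assert net.ncell == 1.0
    rng = np.random.default_rng(seed)
    evaluator = FluxEvaluator(net, model.rate_laws, model.params)
    mets = net.metabolites
    met_pos = {m.id: i for i, m in enumerate(mets)}
    sym = set(net.symmetric_metabolites)
    rev = {m.id: _reverse_bits_perm(m.n_carbons) for m in mets if m.labelable}

    pools: dict[str, np.ndarray] = {}
    counts = np.zeros(len(mets))
    const_frac: dict[str, np.ndarray] = {}
    for m in mets:
        c0 = m.initial_concentration
        counts[met_pos[m.id]] = c0 * n_per_mM
        if not m.labelable:
            continue
        frac = condition.initial_fractions(m.id, m.n_carbons)
        if m.constant:
            const_frac[m.id] = frac
            continue
        n = int(round(c0 * n_per_mM))
        pools[m.id] = rng.choice(len(frac), size=n, p=frac).astype(np.int64)

    def draw_sub(met_id: str, n_ev: int) -> np.ndarray | None:
        """Remove n_ev random molecules; returns their masks."""
        met = net.metabolite_index[met_id]
        if met.constant:
            if met_id in const_frac:
                masks = rng.choice(len(const_frac[met_id]), size=n_ev,
                                   p=const_frac[met_id]).astype(np.int64)
            else:
                masks = None
            return masks
        if met.labelable:
            pool = pools[met_id]
            if n_ev > len(pool):
                n_ev = len(pool)
            idx = np.unique(rng.integers(len(pool), size=n_ev))
            masks = pool[idx].copy()
            keep = np.ones(len(pool), dtype=bool)
            keep[idx] = False
            pools[met_id] = pool[keep]
            counts[met_pos[met_id]] -= len(idx)
            return masks
        counts[met_pos[met_id]] -= n_ev
        return None

    steps = int(round(t_end / dt))
    for _ in range(steps):
        conc = counts / n_per_mM
        for m in mets:
            if m.constant:
                conc[met_pos[m.id]] = m.initial_concentration
        vf, vr = evaluator(conc)
        for j, r in enumerate(net.reactions):
            for J, sub_side, prod_side, amap in (
                (vf[j], r.substrates, r.products, r.atom_map),
                (vr[j], r.products, r.substrates,
                 r.atom_map.inverted() if r.atom_map else None),
            ):
                if J <= 0:
                    continue
                n_ev = rng.poisson(J * dt * n_per_mM)
                if n_ev == 0:
                    continue
                # draw substrate molecules (slot = one molecule instance)
                slot_masks: dict = {}
                actual = n_ev
                from tracekin.network import Slot

                for met_id, coef in sub_side:
                    for occ in range(1, coef + 1):
                        masks = draw_sub(met_id, n_ev)
                        if masks is not None:
                            actual = min(actual, len(masks))
                        slot_masks[Slot(met_id, occ)] = masks
                # truncate to a common event count
                for k, v in slot_masks.items():
                    if v is not None:
                        slot_masks[k] = v[:actual]
                # random orientation for symmetric substrates
                for k, v in slot_masks.items():
                    if v is not None and k.met in sym:
                        flip = rng.random(len(v)) < 0.5
                        v[flip] = rev[k.met][v[flip]]
                # route carbons
                prod_masks: dict = {}
                if amap is not None:
                    for (s, sc), (p, pc) in amap.entries.items():
                        src = slot_masks.get(s)
                        if src is None:
                            continue
                        tgt = prod_masks.setdefault(
                            p, np.zeros(actual, dtype=np.int64)
                        )
                        tgt |= ((src >> (sc - 1)) & 1) << (pc - 1)
                for met_id, coef in prod_side:
                    met = net.metabolite_index[met_id]
                    for occ in range(1, coef + 1):
                        if met.constant:
                            continue
                        if met.labelable:
                            masks = prod_masks.get(
                                Slot(met_id, occ),
                                np.zeros(actual, dtype=np.int64),
                            )
                            if met_id in sym:
                                flip = rng.random(len(masks)) < 0.5
                                masks = masks.copy()
                                masks[flip] = rev[met_id][masks[flip]]
                            pools[met_id] = np.concatenate(
                                [pools[met_id], masks]
                            )
                            counts[met_pos[met_id]] += len(masks)
                        else:
                            counts[met_pos[met_id]] += actual
    return {
        met_id: np.bincount(pool,
                            minlength=2**net.metabolite_index[met_id].n_carbons)
        for met_id, pool in pools.items()
    }


def mc_mid(counts: np.ndarray) -> tuple[np.ndarray, int]:
    """Whole-molecule MID and pool size from a mask-count vector."""
    n = int(np.log2(len(counts)))
    weights = np.array([bin(m).count("1") for m in range(len(counts))])
    total = counts.sum()
    mid = np.zeros(n + 1)
    np.add.at(mid, weights, counts)
    return mid / max(total, 1), int(total)
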