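"""Presence/absence simulation with per-branch planted gain/loss events."""

from __future__ import annotations

import numpy as np

from ..gene_flux import PresenceMatrix
from .history import OUTGROUP, SpeciesHistory
from .sequences import SimTruth

__all__ = ["sim_presence"]


def sim_presence(
    history: SpeciesHistory,
    n_groups: int,
    loss_rate: float,
    gain_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[PresenceMatrix, SimTruth]:
    """Binary gene-occurrence matrix over the subgenome tips + diploids.

    Each branch of the (outgroup-free) tree draws Poisson(*rate*) events per
    group; a loss flips presence to 0, a gain restores it.  Requires
    ``loss_rate >= gain_rate >= 0`` (loss-dominated flux).  Truth records
    one entry per realized event.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if loss_rate < gain_rate:
        raise ValueError("loss_rate must be >= gain_rate")
    tips = [t for t in history.tip_names if t != OUTGROUP]
    tree = history.prune_to(tips).root if OUTGROUP in history.tip_names else history.root

    rng = np.random.default_rng([seed, 0])
    truth = SimTruth()
    width = max(4, len(str(n_groups)))
    group_ids = [f"og{g:0{width}d}" for g in range(n_groups)]
    tip_names = [n.name for n in tree.leaves()]
    matrix = np.ones((n_groups, len(tip_names)), dtype=np.int8)
    tip_index = {t: i for i, t in enumerate(tip_names)}

    for gi, group in enumerate(group_ids):
        states = {tree.name: 1}
        for node in tree.walk():
            if node.parent is None:
                continue
            state = states[node.parent.name]
            if gain_rate > 0 and rng.poisson(gain_rate) > 0 and state == 0:
                state = 1
                truth.presence_events.append(
                    {"group": group, "branch": node.name, "type": "gain"}
                )
            if loss_rate > 0 and rng.poisson(loss_rate) > 0 and state == 1:
                state = 0
                truth.presence_events.append(
                    {"group": group, "branch": node.name, "type": "loss"}
                )
            states[node.name] = state
            if node.is_leaf:
                matrix[gi, tip_index[node.name]] = state
    return PresenceMatrix(group_ids, tip_names, matrix), truth
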