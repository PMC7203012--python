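"""Codon-alignment simulator with planted branch lengths and dN/dS.

Codon sites evolve by a nucleotide Jukes–Cantor proposal process; proposed
changes are accepted with probability 1 when synonymous and ``omega`` when
nonsynonymous, and rejected when they would create a stop codon.  Under this
scheme the expected number of accepted synonymous changes per synonymous
site on a branch equals the branch's nominal length in substitutions/site,
so dating by ``T = Ks / 2r`` round-trips exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .._codon import CODONS, STOP_CODONS, is_stop, translate
from .history import SpeciesHistory, TreeNode

__all__ = ["AlignmentSet", "GeneTruth", "SimTruth", "sim_alignments"]

_NON_STOP = [c for c in CODONS if c not in STOP_CODONS]
_NUCS = "ACGT"
_ALT = {n: [m for m in _NUCS if m != n] for n in _NUCS}


@dataclass
class AlignmentSet:
    """Per-gene alignments: ``genes[gene_id][tip_name] -> aligned sequence``."""

    genes: dict[str, dict[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __getitem__(self, gene: str) -> dict[str, str]:
        return self.genes[gene]

    def tips(self) -> list[str]:
        first = next(iter(self.genes.values()), {})
        return list(first)


@dataclass
class GeneTruth:
    gene: str
    omega: float
    #: expected substitutions/site on the branch above each named node
    branch_lengths: dict[str, float]


@dataclass
class SimTruth:
    """Planted ground truth accumulated by the simulators."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    presence_events: list[dict] = field(default_factory=list)
    ltr_ages: dict[str, float] = field(default_factory=dict)
    blocks: list[tuple[int, int]] = field(default_factory=list)
    effects: dict = field(default_factory=dict)

    def merge(self, other: "SimTruth") -> "SimTruth":
        self.genes.update(other.genes)
        self.presence_events.extend(other.presence_events)
        self.ltr_ages.update(other.ltr_ages)
        self.blocks.extend(other.blocks)
        self.effects.update(other.effects)
        return self


def _resolve_omega(
    omega_spec: float | Sequence[float] | Callable[[np.random.Generator], float],
    k: int,
    rng: np.random.Generator,
) -> float:
    if callable(omega_spec):
        omega = float(omega_spec(rng))
    elif isinstance(omega_spec, (int, float)):
        omega = float(omega_spec)
    else:
        omega = float(omega_spec[k % len(omega_spec)])
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return omega


def _evolve_branch(
    codons: list[str], d: float, omega: float, rng: np.random.Generator
) -> list[str]:
    """Apply the proposal process for a branch of nominal length *d*."""
    codons = list(codons)
    n_sites = 3 * len(codons)
    n_events = rng.poisson(d * n_sites)
    if n_events == 0:
        return codons
    sites = rng.integers(0, n_sites, size=n_events)
    alt_picks = rng.integers(0, 3, size=n_events)
    accept_draws = rng.random(size=n_events)
    for s, a, u in zip(sites, alt_picks, accept_draws):
        ci, pos = divmod(int(s), 3)
        codon = codons[ci]
        alt = _ALT[codon[pos]][a]
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if is_stop(mutant):
            continue
        if translate(mutant) != translate(codon) and u >= omega:
            continue
        codons[ci] = mutant
    return codons


def sim_alignments(
    history: SpeciesHistory,
    n_genes: int,
    n_codons: int,
    omega_spec: float | Sequence[float] | Callable[[np.random.Generator], float] = 1.0,
    seed: int | None = None,
    gap_rate: float = 0.0,
    taxa: Sequence[str] | None = None,
) -> tuple[AlignmentSet, SimTruth]:
    """Simulate per-gene codon alignments on *history*.

    Gene ``k`` draws from the stream ``default_rng([seed, k])`` so each gene
    is reproducible in isolation.  ``taxa`` restricts the simulation to a
    pruned subtree (expected per-branch substitutions preserved).

    Returns alignments (stop-free, optionally gapped) plus per-gene truth.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must be in [0, 1)")
    if taxa is not None:
        history = history.prune_to(list(taxa))

    aln = AlignmentSet()
    truth = SimTruth()
    width = max(4, len(str(n_genes)))
    for k in range(n_genes):
        rng = np.random.default_rng([seed, k])
        gene = f"g{k:0{width}d}"
        omega = _resolve_omega(omega_spec, k, rng)
        root_codons = [_NON_STOP[i] for i in rng.integers(0, len(_NON_STOP), n_codons)]

        seqs: dict[str, str] = {}
        branch_lengths: dict[str, float] = {}

        def descend(node: TreeNode, codons: list[str]) -> None:
            for child in node.children:
                d = history.branch_subs_per_site(child)
                branch_lengths[child.name] = d
                child_codons = _evolve_branch(codons, d, omega, rng)
                if child.is_leaf:
                    seqs[child.name] = "".join(child_codons)
                else:
                    descend(child, child_codons)

        descend(history.root, root_codons)

        if gap_rate > 0:
            tips = list(seqs)
            cols = np.nonzero(rng.random(3 * n_codons) < gap_rate)[0]
            victims = rng.integers(0, len(tips), size=len(cols))
            arrays = {t: bytearray(seqs[t], "ascii") for t in tips}
            for col, v in zip(cols, victims):
                arrays[tips[v]][col] = ord("-")
            seqs = {t: arrays[t].decode("ascii") for t in tips}

        aln.genes[gene] = seqs
        truth.genes[gene] = GeneTruth(gene, omega, branch_lengths)
    return aln, truth
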