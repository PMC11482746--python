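"""Reference ensembles: brute-force and shared-prefix microstate enumeration.

Both methods build all 2**N charge microstates explicitly and serve as
correctness oracles (and cost baselines) for the streaming engine in
:mod:`medoc.engine`, which never materializes individual microstates.

* :func:`brute_force_ensemble` evaluates every microstate independently —
  the O(2**N) baseline.
* :func:`shared_prefix_ensemble` walks the binary prefix tree of protonation
  states in sequence order, so the free energy of a shared prefix (e.g. the
  "Ee" start common to the microstates "Eee" and "EeE") is computed exactly
  once and extended one residue at a time.

``operation_count`` counts energy additions only: one addition per released
site whose context free energy is accumulated into a microstate (prefix)
energy.  Bookkeeping, lookups and proton-free extensions are not counted, so
the numbers are comparable across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .database import ContextDatabase, site_delta_tables
from .errors import EngineError
from .sequence import Mesostate, SequenceRecord, microstate_label
from .thermo import DEFAULT_THERMO, ThermoParams

#: Largest N for which explicit enumeration is permitted.
DEFAULT_CAP = 20


@dataclass
class MicrostateEnsemble:
    """All 2**N microstates of a record, in prefix-tree (DFS, 0-before-1) order."""

    record: SequenceRecord
    states: np.ndarray  # (2**N, N) uint8
    G: np.ndarray  # (2**N,) standard free energies, kcal/mol
    operation_count: int
    n_extensions: int = 0  # prefix-tree edges walked (shared-prefix method only)

    @property
    def n_released(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def net_charge(self) -> np.ndarray:
        return self.record.q_max - self.n_released

    def to_dataframe(self) -> pd.DataFrame:
        labels = [microstate_label(self.record, s) for s in self.states]
        return pd.DataFrame(
            {
                "label": labels,
                "n_released": self.n_released,
                "net_charge": self.net_charge,
                "G_standard": self.G,
            }
        )


def _check_cap(record: SequenceRecord, cap: int) -> None:
    if record.n_sites > cap:
        raise EngineError(
            f"{record.n_sites} ionizable sites exceed the enumeration cap ({cap}); "
            "use the streaming engine (medoc.engine) instead"
        )


def _all_states(n: int) -> np.ndarray:
    """All binary vectors of length n, site 0 as the most significant bit."""
    idx = np.arange(2 ** n, dtype=np.uint32)
    out = np.empty((2 ** n, n), dtype=np.uint8)
    for j in range(n):
        out[:, j] = (idx >> (n - 1 - j)) & 1
    return out


def brute_force_ensemble(
    db: ContextDatabase, record: SequenceRecord, cap: int = DEFAULT_CAP
) -> MicrostateEnsemble:
    """Evaluate every microstate independently (O(2**N) energy additions)."""
    _check_cap(record, cap)
    n = record.n_sites
    states = _all_states(n)
    tables = site_delta_tables(db, record)
    G = np.zeros(2 ** n)
    for i, tab in enumerate(tables):
        ctx = np.zeros(2 ** n, dtype=np.int64)
        k = len(tab.dep_sites)
        for j, dep in enumerate(tab.dep_sites):
            ctx |= states[:, dep].astype(np.int64) << (k - 1 - j)
        G += states[:, i] * tab.table()[ctx]
    ops = int(states.sum())  # one addition per released site per microstate
    return MicrostateEnsemble(record=record, states=states, G=G, operation_count=ops)


def shared_prefix_ensemble(
    db: ContextDatabase, record: SequenceRecord, cap: int = DEFAULT_CAP
) -> MicrostateEnsemble:
    """Dynamic building of the ensemble: extend shared prefixes one site at a time.

    Walks the binary prefix tree depth-first (protonated branch before the
    deprotonated branch) so the ensemble ordering matches
    :func:`brute_force_ensemble`.  Each prefix free energy is computed once;
    ``n_extensions`` counts all tree edges (2**(N+1) - 2), while
    ``operation_count`` counts only the edges that add a deprotonation free
    energy (2**N - 1).
    """
    _check_cap(record, cap)
    n = record.n_sites
    tables = site_delta_tables(db, record)
    states_out = np.empty((2 ** n, n), dtype=np.uint8)
    G_out = np.empty(2 ** n)
    ops = 0
    exts = 0
    leaf = 0
    prefix = np.zeros(n, dtype=np.uint8)
    # iterative DFS; stack holds (depth, branch, G_prefix)
    stack = [(0, None, 0.0)]
    if n == 0:
        states_out = np.zeros((1, 0), dtype=np.uint8)
        G_out = np.zeros(1)
        return MicrostateEnsemble(record, states_out, G_out, 0, 0)
    while stack:
        depth, branch, g = stack.pop()
        if branch is not None:
            exts += 1
            prefix[depth - 1] = branch
            if branch == 1:
                tab = tables[depth - 1]
                g += tab.lookup(prefix[list(tab.dep_sites)])
                ops += 1
        if depth == n:
            states_out[leaf] = prefix
            G_out[leaf] = g
            leaf += 1
            continue
        # push 1-branch first so the 0-branch is explored first (LIFO)
        stack.append((depth + 1, 1, g))
        stack.append((depth + 1, 0, g))
    assert leaf == 2 ** n
    return MicrostateEnsemble(
        record=record, states=states_out, G=G_out, operation_count=ops, n_extensions=exts
    )


def mesostate_free_energies_from_ensemble(
    ensemble: MicrostateEnsemble, thermo: ThermoParams = DEFAULT_THERMO
):
    """Aggregate an explicit ensemble into mesostates via the F operator.

    Returns ``(mesostates, intra_populations)`` where ``intra_populations[q]``
    is the Boltzmann distribution over the member microstates of mesostate q
    (in ensemble order); each vector sums to 1.
    """
    record = ensemble.record
    n = record.n_sites
    rt = thermo.RT
    nrel = ensemble.n_released
    mesostates = []
    intra = []
    for q in range(n + 1):
        g = ensemble.G[nrel == q]
        lse = logsumexp(-g / rt)
        mesostates.append(Mesostate(n_released=q, net_charge=record.q_max - q, G=-rt * lse))
        intra.append(np.exp(-g / rt - lse))
    return mesostates, intra


__all__ = [
    "DEFAULT_CAP",
    "MicrostateEnsemble",
    "brute_force_ensemble",
    "shared_prefix_ensemble",
    "mesostate_free_energies_from_ensemble",
]
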