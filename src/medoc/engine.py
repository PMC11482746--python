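"""Streaming, exact computation of mesostate free energies (the MEDOC engine).

The engine walks the ionizable sites N-to-C and maintains, instead of the
2**N individual microstates, the aggregated free energy

    G[q, c] = F over all prefix microstates with q released protons that end
              in trailing context c

where ``F(G_1..G_n) = -RT ln(sum_i exp(-G_i / RT))`` is the overall free
energy of a set of states and the trailing context c is the tuple of
protonation states of the most recent tracked sites.  A site stays tracked
only while it can still modulate the deprotonation free energy of an
upcoming site, i.e. while its sequence distance to the next site is at most
the database window; once it expires, contexts differing only in that bit
are recombined with F.  At every step each entry branches in two: the new
site either keeps its proton (q unchanged, append bit 0) or releases it
(q+1, append bit 1, add the context-dependent free energy of the new site).
After the last site, F over the surviving contexts of each q yields the
exact mesostate free energies G_q — the full partition function in N+1
numbers, at polynomial cost.

The site-specific engine carries the same propagation once per already-seen
position p and protonation state s of that position, yielding the overall
free energy of all microstates of mesostate q with site p in state s — the
quantities behind per-residue titration curves and apparent pKa values.

Internally everything is stored as log Boltzmann weights L = -G/RT and
combined with numpy's max-shifted ``logaddexp``; absent combinations are
``-inf`` in L (``+inf`` free energy) and never pollute a merge.  Iteration
order and merge order are fixed, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp as _lse

from .database import ContextDatabase, site_delta_tables
from .errors import EngineError
from .sequence import Mesostate, SequenceRecord
from .thermo import DEFAULT_THERMO, ThermoParams

def F(free_energies: Sequence[float], thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Overall free energy of a set of states: -RT ln sum exp(-G_i/RT).

    Max-shift stabilized; the result never exceeds the smallest input.
    Entries at +inf (absent states) are ignored; an empty input is rejected.
    """
    g = np.asarray(free_energies, dtype=float)
    if g.size == 0:
        raise EngineError("F requires at least one free energy")
    if np.any(np.isneginf(g)) or np.any(np.isnan(g)):
        raise EngineError("F requires finite (or +inf) free energies")
    rt = thermo.RT
    return float(-rt * _lse(-g / rt))


@dataclass
class OpCounter:
    """Energy-operation tally: additions of context free energies and F merges."""

    additions: int = 0
    merges: int = 0

    @property
    def total(self) -> int:
        return self.additions + self.merges


@dataclass
class GlobalResult:
    """Mesostate free energies from the global-scope engine."""

    record: SequenceRecord
    G: np.ndarray  # (N+1,) kcal/mol; G[0] == 0 by the reference convention
    thermo: ThermoParams
    ops: OpCounter

    @property
    def mesostates(self) -> List[Mesostate]:
        qmax = self.record.q_max
        return [
            Mesostate(n_released=q, net_charge=qmax - q, G=float(g))
            for q, g in enumerate(self.G)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.record.q_max - np.arange(self.record.n_sites + 1),
                "n_released": np.arange(self.record.n_sites + 1),
                "G_standard": self.G,
            }
        )


@dataclass
class SiteResult:
    """Per-site, per-state mesostate free energies from the site-scope engine.

    ``G[p, s, q]`` is the overall standard free energy of all microstates of
    mesostate q in which site p is in state s; impossible combinations
    (e.g. s=1 with q=0) are +inf.
    """

    record: SequenceRecord
    G: np.ndarray  # (N, 2, N+1)
    global_G: np.ndarray  # (N+1,) — the global engine result, for free
    thermo: ThermoParams
    ops: OpCounter

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p, site in enumerate(self.record.sites):
            for s in (0, 1):
                for q in range(self.record.n_sites + 1):
                    g = self.G[p, s, q]
                    if np.isfinite(g):
                        rows.append(
                            {
                                "position": site.position + 1,
                                "residue": site.residue_type,
                                "state": s,
                                "q": self.record.q_max - q,
                                "n_released": q,
                                "G_standard": g,
                            }
                        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared propagation machinery


class _Steps:
    """Precomputed per-site schedule: expirations and context dE vectors."""

    def __init__(self, db, record, window, context_pad):
        if window is None:
            window = db.window
        if window > db.window:
            raise EngineError(
                f"requested window {window} exceeds the database window {db.window}"
            )
        self.window = window
        self.keep = window + max(0, int(context_pad))
        self.tables = site_delta_tables(db, record, window=window)
        self.record = record

    def expirations(self, tracked: list, i: int) -> int:
        """How many leading tracked sites to expire before branching site i."""
        pos = self.record.sites[i].position
        n = 0
        while n < len(tracked) and pos - self.record.sites[tracked[n]].position > self.keep:
            n += 1
        return n

    def de_vector(self, i: int, tracked: list) -> np.ndarray:
        """dE of site i over all 2**len(tracked) contexts.

        Context bit j (LSB = oldest tracked site) is the state of
        ``tracked[j]``.  Tracked sites outside the window (retained only
        through context_pad) do not influence the value.
        """
        tab = self.tables[i]
        k = len(tracked)
        out = np.full(2 ** k, tab.base)
        dep_lookup = {s: j for j, s in enumerate(tab.dep_sites)}
        for jt, s in enumerate(tracked):
            j = dep_lookup.get(s)
            if j is None:
                continue  # padded-out site: no effect on dE
            bit = (np.arange(2 ** k) >> jt) & 1
            out = out + tab.contrib[j, :][bit]
        return out


def _count_pos(a: np.ndarray) -> int:
    return int(np.count_nonzero(a))


#: Steps between explicit renormalizations of the scaled weights.
_RENORM_EVERY = 16


def _propagate(steps: _Steps, record, thermo, with_sites: bool, count_ops: bool):
    """Shared N-to-C propagation in max-shifted scaled weight space.

    The aggregated tables are stored as nonnegative weights ``W`` together
    with one log-offset per mesostate row, ``off[q]``: the true log Boltzmann
    weight of an entry is ``log(W) + off[q]``.  This is the F operator's
    max-shift maintained incrementally — offsets track the running row
    maximum (re-anchored to it every few steps), so context merges are plain
    additions and the release branch is a vector multiply, while overflow is
    impossible and underflow only affects states hundreds of RT above their
    mesostate's dominant microstates.  A weight of exactly 0 marks an absent
    combination (free energy +inf).

    Returns ``(G_global, G_site or None, ops)``.
    """
    rt = thermo.RT
    N = record.n_sites
    ops = OpCounter()
    Wg = np.ones((1, 1))  # global weights, axes (q, context); newest bit = MSB
    off = np.zeros(1)  # per-q log offsets (shared by the site tables)
    S = np.empty((0, 2, 1, 1)) if with_sites else None
    tracked: list = []
    for i in range(N):
        for _ in range(steps.expirations(tracked, i)):
            # dropping the oldest (LSB) context bit merges adjacent index pairs
            if count_ops:
                ops.merges += _count_pos(np.minimum(Wg[:, 0::2], Wg[:, 1::2]))
                if with_sites:
                    ops.merges += _count_pos(np.minimum(S[..., 0::2], S[..., 1::2]))
            Wg = Wg[:, 0::2] + Wg[:, 1::2]
            if with_sites:
                S = S[..., 0::2] + S[..., 1::2]
            tracked.pop(0)
        dE = steps.de_vector(i, tracked)
        nq, C = Wg.shape
        release = np.exp(-dE / rt)  # (C,)
        if count_ops:
            ops.additions += _count_pos(Wg) + (_count_pos(S) if with_sites else 0)
        # reconcile the two parent offsets of every new row
        off2 = np.empty(nq + 1)
        off2[0] = off[0]
        off2[nq] = off[nq - 1]
        if nq > 1:
            off2[1:nq] = np.maximum(off[1:], off[: nq - 1])
        keep_scale = np.exp(off - off2[:nq])  # (nq,)
        rel_scale = np.exp(off - off2[1:])[:, None] * release[None, :]  # (nq, C)
        Wg2 = np.empty((nq + 1, 2 * C))
        np.multiply(Wg, keep_scale[:, None], out=Wg2[:nq, :C])
        Wg2[nq, :C] = 0.0
        np.multiply(Wg, rel_scale, out=Wg2[1:, C:])
        Wg2[0, C:] = 0.0
        if with_sites:
            S2 = np.empty((i + 1, 2, nq + 1, 2 * C))
            # existing positions branch with the global step
            np.multiply(S, keep_scale[None, None, :, None], out=S2[:i, :, :nq, :C])
            S2[:i, :, nq, :C] = 0.0
            np.multiply(S, rel_scale[None, None, :, :], out=S2[:i, :, 1:, C:])
            S2[:i, :, 0, C:] = 0.0
            # the new position inherits from the global aggregate, split by branch
            S2[i, :, :, :] = 0.0
            S2[i, 0, :nq, :C] = Wg2[:nq, :C]
            S2[i, 1, 1:, C:] = Wg2[1:, C:]
            S = S2
        Wg = Wg2
        off = off2
        tracked.append(i)
        if (i + 1) % _RENORM_EVERY == 0 or i == N - 1:
            # re-anchor each row's offset to its current global maximum
            rowmax = Wg.max(axis=1)
            inv = 1.0 / rowmax
            Wg *= inv[:, None]
            if with_sites:
                S *= inv[None, None, :, None]
            off += np.log(rowmax)
    with np.errstate(divide="ignore"):
        G_global = -rt * (np.log(Wg.sum(axis=1)) + off)
        G_global[0] = 0.0  # the reference (fully protonated) state, exactly
        if with_sites:
            if N == 0:
                G_site = np.empty((0, 2, 1))
            else:
                G_site = -rt * (np.log(S.sum(axis=3)) + off[None, None, :])
                # the q=0 mesostate is the single fully protonated microstate
                G_site[:, 0, 0] = 0.0
        else:
            G_site = None
    return G_global, G_site, ops


def global_mesostate_free_energies(
    db: ContextDatabase,
    record: SequenceRecord,
    thermo: ThermoParams = DEFAULT_THERMO,
    window: int | None = None,
    context_pad: int = 0,
    count_ops: bool = False,
) -> GlobalResult:
    """Exact mesostate free energies G_q for q = 0..N, without enumeration.

    ``context_pad`` retains expired context bits for extra sequence distance;
    it changes cost but (by window locality) not the result, and exists for
    testing.  ``count_ops`` tallies energy additions and F merges.
    """
    steps = _Steps(db, record, window, context_pad)
    G, _, ops = _propagate(steps, record, thermo, with_sites=False, count_ops=count_ops)
    return GlobalResult(record=record, G=G, thermo=thermo, ops=ops)


def site_mesostate_free_energies(
    db: ContextDatabase,
    record: SequenceRecord,
    thermo: ThermoParams = DEFAULT_THERMO,
    window: int | None = None,
    context_pad: int = 0,
    count_ops: bool = False,
) -> SiteResult:
    """Per-(position, state, mesostate) overall free energies, exactly.

    Runs the global propagation while carrying, for every already-seen site p
    and state s, the same aggregated table restricted to prefixes with site p
    in state s.  When site i is introduced its (p=i, s) tables are inherited
    from the global aggregate, split by the branch taken.  F-combining the
    s=0 and s=1 tables of any p reproduces the global result (refinement
    identity), which holds here by construction.
    """
    steps = _Steps(db, record, window, context_pad)
    G_global, G_site, ops = _propagate(steps, record, thermo, with_sites=True, count_ops=count_ops)
    return SiteResult(record=record, G=G_site, global_G=G_global, thermo=thermo, ops=ops)


def mass_conservation_log(result: GlobalResult) -> float:
    """log of the total Boltzmann mass sum_q exp(-G_q/RT); equals N ln 2 when
    all microstates are isoenergetic, and must equal the log-mass of the
    explicit ensemble in general."""
    rt = result.thermo.RT
    return float(_lse(-result.G / rt))


__all__ = [
    "F",
    "OpCounter",
    "GlobalResult",
    "SiteResult",
    "global_mesostate_free_energies",
    "site_mesostate_free_energies",
    "mass_conservation_log",
]
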