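"""Context-dependent deprotonation free-energy database (implicit/additive model).

The free-energy cost of deprotonating a titratable residue depends on its
local sequence context.  The additive ("implicit") model decomposes it as

    dE(site | context) = [intrinsic(type) + offset(type)]
                         + scale(type) * sum_over_neighbors pair(central, neighbor,
                                                                neighbor_state, signed_offset)

where the sum runs over all sequence neighbors within ``window`` residues on
each side.  Because microstate free energies are assembled along the N-to-C
thermodynamic path (residues release their protons in sequence order), a
right-side neighbor has never yet released its proton when a residue's
contribution is added — so right neighbors, and left neighbors that are not
titratable, are always looked up in the protonated state.  Only left
titratable neighbors within the window carry a state-dependent term.

``(offset(type), scale(type))`` are the per-residue-type rescaling factors
fitted by :mod:`medoc.calibrate`; an uncalibrated database has (0, 1).

The package ships no simulation-derived pair terms; :func:`generate_synthetic_db`
builds a database from a screened-electrostatics model plus literature
model-compound intrinsic pKa values (see ``data/model_pka.json``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .errors import DatabaseError, SequenceError
from .sequence import (
    AA_ALPHABET,
    CTERM,
    DEFAULT_CONFIG,
    NTERM,
    IonizationConfig,
    SequenceRecord,
)
from .thermo import DEFAULT_THERMO, LN10, ThermoParams

DB_VERSION = "medoc-db-1"

#: Protonation-state codes used in pair-term keys.
PROTONATED = 0
DEPROTONATED = 1

_STATE_NAMES = {PROTONATED: "protonated", DEPROTONATED: "deprotonated"}
_STATE_CODES = {v: k for k, v in _STATE_NAMES.items()}

PairKey = Tuple[str, str, int, int]  # (central, neighbor, neighbor_state, offset)


def load_model_pkas() -> Dict[str, float]:
    """Shipped model-compound intrinsic pKa table (overridable data)."""
    text = resources.files("medoc.data").joinpath("model_pka.json").read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


@dataclass
class ContextDatabase:
    """Additive context free-energy database.

    ``pair_terms`` maps ``(central_type, neighbor_type, neighbor_state, offset)``
    to an additive contribution in kcal/mol; ``offset`` is the signed sequence
    distance of the neighbor (never 0), ``neighbor_state`` is 0 (protonated)
    or 1 (deprotonated).  Non-titratable neighbor types appear only in the
    protonated state.
    """

    window: int
    intrinsic: Dict[str, float]
    pair_terms: Dict[PairKey, float]
    rescale: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    config: IonizationConfig = DEFAULT_CONFIG
    version: str = DB_VERSION

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.window < 0:
            raise DatabaseError("window must be >= 0")
        ionizable = self.config.ionizable | {NTERM, CTERM}
        for key, value in self.pair_terms.items():
            central, neighbor, state, offset = key
            if offset == 0:
                raise DatabaseError(f"pair term with offset 0: {key}")
            if abs(offset) > self.window:
                raise DatabaseError(f"pair term outside the window: {key}")
            if state not in (PROTONATED, DEPROTONATED):
                raise DatabaseError(f"invalid neighbor state in pair term: {key}")
            if neighbor not in ionizable and state == DEPROTONATED:
                raise DatabaseError(
                    f"non-titratable neighbor {neighbor!r} with deprotonated state: {key}"
                )
            if not math.isfinite(value):
                raise DatabaseError(f"non-finite pair term: {key}")
        for t, v in self.intrinsic.items():
            if not math.isfinite(v):
                raise DatabaseError(f"non-finite intrinsic term for {t!r}")
        for t, (off, sc) in self.rescale.items():
            if not (math.isfinite(off) and math.isfinite(sc)):
                raise DatabaseError(f"non-finite rescale entry for {t!r}")

    # -- accessors ---------------------------------------------------------

    def rescale_for(self, residue_type: str) -> Tuple[float, float]:
        return self.rescale.get(residue_type, (0.0, 1.0))

    def intrinsic_term(self, residue_type: str) -> float:
        try:
            base = self.intrinsic[residue_type]
        except KeyError:
            raise DatabaseError(f"no intrinsic term for residue type {residue_type!r}")
        return base + self.rescale_for(residue_type)[0]

    def pair(self, central: str, neighbor: str, neighbor_state: int, offset: int) -> float:
        key = (central, neighbor, neighbor_state, offset)
        try:
            return self.pair_terms[key]
        except KeyError:
            raise DatabaseError(
                "missing pair term (central={!r}, neighbor={!r}, state={}, offset={:+d})".format(
                    central, neighbor, _STATE_NAMES.get(neighbor_state, neighbor_state), offset
                )
            )

    def with_rescale(self, rescale: Mapping[str, Tuple[float, float]]) -> "ContextDatabase":
        return replace(self, rescale=dict(rescale))


# ---------------------------------------------------------------------------
# Context evaluation


def _neighbor_identity(record: SequenceRecord, pos: int):
    """Residue/pseudo-site type at sequence position ``pos``, or None off-chain.

    Returns ``(type_code, site_index_or_None)``.
    """
    hit = record.site_at(pos)
    if hit is not None:
        idx, site = hit
        return site.residue_type, idx
    if 0 <= pos < len(record.residues):
        return record.residues[pos], None
    return None, None


def delta_E(
    db: ContextDatabase,
    record: SequenceRecord,
    site_index: int,
    left_states: Sequence[int],
) -> float:
    """Context-dependent deprotonation free energy of one site.

    ``left_states`` assigns a protonation state to every ionizable site
    preceding ``site_index`` (entries beyond the window are ignored).  Right
    neighbors and non-titratable left neighbors are looked up protonated.
    """
    if not 0 <= site_index < record.n_sites:
        raise SequenceError(f"site index {site_index} out of range (N={record.n_sites})")
    left_states = list(left_states)
    if len(left_states) < site_index:
        raise SequenceError(
            f"left_states must cover the {site_index} sites preceding site {site_index}"
        )
    site = record.sites[site_index]
    central = site.residue_type
    _, scale = db.rescale_for(central)
    total_pair = 0.0
    w = db.window
    for off in range(-w, w + 1):
        if off == 0:
            continue
        ntype, nsite = _neighbor_identity(record, site.position + off)
        if ntype is None:
            continue
        if nsite is not None and nsite < site_index:
            state = int(left_states[nsite])
        else:
            state = PROTONATED
        total_pair += db.pair(central, ntype, state, off)
    return db.intrinsic_term(central) + scale * total_pair


def microstate_free_energy(
    db: ContextDatabase, record: SequenceRecord, states: Sequence[int]
) -> float:
    """Standard free energy of a microstate along the N-to-C path.

    Sum, over sites with state 1 in sequence order, of that site's
    :func:`delta_E` with the left context taken from ``states``.  The fully
    protonated vector returns exactly 0 (the reference state).
    """
    states = list(states)
    if len(states) != record.n_sites:
        raise SequenceError(
            f"state vector length {len(states)} != number of sites {record.n_sites}"
        )
    g = 0.0
    for i, s in enumerate(states):
        if s:
            g += delta_E(db, record, i, states[:i])
    return g


@dataclass(frozen=True)
class SiteDeltaTable:
    """Precomputed deprotonation free energies of one site over left contexts.

    ``dep_sites`` lists the indices of the titratable sites within the window
    to the left, in sequence order.  ``lookup(bits)`` with one state bit per
    dep site (oldest first) returns delta_E for that context.
    """

    site_index: int
    dep_sites: tuple  # left in-window ionizable site indices, ascending
    base: float  # rescaled intrinsic + scaled state-independent pair sum
    contrib: np.ndarray  # shape (len(dep_sites), 2): scaled pair term per state

    def lookup(self, bits: Sequence[int]) -> float:
        g = self.base
        for j, b in enumerate(bits):
            g += self.contrib[j, int(b)]
        return g

    def table(self) -> np.ndarray:
        """Dense dE over all 2**k contexts; bit j of the index (MSB-first
        over ``dep_sites``) is the state of dep site j."""
        k = len(self.dep_sites)
        out = np.full(2 ** k, self.base)
        for j in range(k):
            bit = (np.arange(2 ** k) >> (k - 1 - j)) & 1
            out += self.contrib[j, :][bit]
        return out


def site_delta_tables(db: ContextDatabase, record: SequenceRecord, window: int | None = None):
    """Per-site context tables used by every engine in the package.

    ``window`` may restrict the evaluation to fewer neighbors than the
    database holds (never more).
    """
    w = db.window if window is None else int(window)
    if w > db.window:
        raise DatabaseError(
            f"requested window {w} exceeds the database window {db.window}"
        )
    tables = []
    for i, site in enumerate(record.sites):
        central = site.residue_type
        _, scale = db.rescale_for(central)
        base = db.intrinsic_term(central)
        dep = []
        dep_offsets = []
        for off in range(-w, w + 1):
            if off == 0:
                continue
            ntype, nsite = _neighbor_identity(record, site.position + off)
            if ntype is None:
                continue
            if nsite is not None and nsite < i:
                dep.append(nsite)
                dep_offsets.append((ntype, off))
            else:
                base += scale * db.pair(central, ntype, PROTONATED, off)
        contrib = np.empty((len(dep), 2))
        for j, (ntype, off) in enumerate(dep_offsets):
            contrib[j, PROTONATED] = scale * db.pair(central, ntype, PROTONATED, off)
            contrib[j, DEPROTONATED] = scale * db.pair(central, ntype, DEPROTONATED, off)
        order = np.argsort(dep, kind="stable")
        tables.append(
            SiteDeltaTable(
                site_index=i,
                dep_sites=tuple(dep[j] for j in order),
                base=base,
                contrib=contrib[order] if len(dep) else contrib,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Synthetic database generator


def generate_synthetic_db(
    config: IonizationConfig = DEFAULT_CONFIG,
    window: int = 5,
    coupling_strength: float = 0.6,
    decay_length: float = 2.0,
    intrinsic_pkas: Mapping[str, float] | None = None,
    neutral_sigma: float = 0.05,
    seed: int = 0,
    thermo: ThermoParams = DEFAULT_THERMO,
) -> ContextDatabase:
    """Build a screened-electrostatics stand-in for a simulation-derived database.

    Intrinsic terms are ``RT ln(10) * pKa_model``.  A neighbor carrying charge
    ``z`` in its looked-up state changes the central deprotonation free energy
    by ``-z * coupling_strength * exp(-|offset| / decay_length)`` — removing a
    proton lowers the central charge by one, so a positive neighbor favors and
    a negative neighbor disfavors deprotonation.  Neutral-state neighbors
    contribute a small type-dependent perturbation drawn reproducibly from
    ``seed``.  Deterministic given (parameters, seed).

    ``coupling_strength`` and ``neutral_sigma`` are in kcal/mol,
    ``decay_length`` in residues.
    """
    if decay_length <= 0:
        raise DatabaseError("decay_length must be positive")
    if window < 0:
        raise DatabaseError("window must be >= 0")
    pkas = dict(load_model_pkas() if intrinsic_pkas is None else intrinsic_pkas)

    site_types = sorted(config.ionizable)
    if config.include_termini:
        site_types += [NTERM, CTERM]
    missing = [t for t in site_types if t not in pkas]
    if missing:
        raise DatabaseError(f"no intrinsic pKa for titratable types: {missing}")
    intrinsic = {t: thermo.pka_to_energy(pkas[t]) for t in site_types}

    def state_charge(t: str, state: int) -> int:
        if t in config.acids or t == CTERM:
            return 0 if state == PROTONATED else -1
        if t in config.bases or t == NTERM:
            return 1 if state == PROTONATED else 0
        return config.fixed_charges.get(t, 0)

    neighbor_types = sorted(AA_ALPHABET)
    if config.include_termini:
        neighbor_types += [NTERM, CTERM]
    titratable = set(site_types)

    rng = np.random.default_rng(seed)
    pair_terms: Dict[PairKey, float] = {}
    # sorted iteration keeps the seeded neutral perturbations reproducible
    for central in site_types:
        for neighbor in neighbor_types:
            states = (PROTONATED, DEPROTONATED) if neighbor in titratable else (PROTONATED,)
            for state in states:
                for off in range(-window, window + 1):
                    if off == 0:
                        continue
                    screen = math.exp(-abs(off) / decay_length)
                    z = state_charge(neighbor, state)
                    if z != 0:
                        value = -z * coupling_strength * screen
                    else:
                        value = rng.normal(0.0, neutral_sigma) * screen
                    pair_terms[(central, neighbor, state, off)] = value
    return ContextDatabase(
        window=window,
        intrinsic=intrinsic,
        pair_terms=pair_terms,
        rescale={},
        config=config,
    )


# ---------------------------------------------------------------------------
# Persistence (versioned JSON)


def save_db(db: ContextDatabase, path) -> None:
    doc = {
        "version": db.version,
        "window": db.window,
        "alphabet": {
            "acids": sorted(db.config.acids),
            "bases": sorted(db.config.bases),
            "include_termini": db.config.include_termini,
            "fixed_charges": dict(db.config.fixed_charges),
        },
        "intrinsic": dict(sorted(db.intrinsic.items())),
        "pair_terms": [
            {
                "central": c,
                "neighbor": n,
                "neighbor_state": _STATE_NAMES[s],
                "offset": o,
                "value": v,
            }
            for (c, n, s, o), v in sorted(db.pair_terms.items())
        ],
        "rescale": {
            t: {"intrinsic_offset": off, "electrostatic_scale": sc}
            for t, (off, sc) in sorted(db.rescale.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_db(path) -> ContextDatabase:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != DB_VERSION:
        raise DatabaseError(
            f"unsupported database version {doc.get('version')!r} (expected {DB_VERSION!r})"
        )
    for key in ("window", "alphabet", "intrinsic", "pair_terms"):
        if key not in doc:
            raise DatabaseError(f"database file missing required field {key!r}")
    alpha = doc["alphabet"]
    config = IonizationConfig(
        acids=frozenset(alpha.get("acids", [])),
        bases=frozenset(alpha.get("bases", [])),
        include_termini=bool(alpha.get("include_termini", False)),
        fixed_charges={str(k): int(v) for k, v in alpha.get("fixed_charges", {}).items()},
    )
    known_types = AA_ALPHABET | {NTERM, CTERM}
    pair_terms: Dict[PairKey, float] = {}
    for row in doc["pair_terms"]:
        try:
            state = _STATE_CODES[row["neighbor_state"]]
            key = (str(row["central"]), str(row["neighbor"]), state, int(row["offset"]))
            value = float(row["value"])
        except (KeyError, TypeError, ValueError) as exc:
            raise DatabaseError(f"malformed pair-term row {row!r}: {exc}")
        if key[0] not in known_types or key[1] not in known_types:
            raise DatabaseError(f"unknown residue type in pair-term row {row!r}")
        if key in pair_terms:
            raise DatabaseError(f"duplicate pair-term key {key}")
        pair_terms[key] = value
    intrinsic = {}
    for t, v in doc["intrinsic"].items():
        if t not in known_types:
            raise DatabaseError(f"unknown residue type {t!r} in intrinsic table")
        intrinsic[t] = float(v)
    rescale = {
        t: (float(r["intrinsic_offset"]), float(r["electrostatic_scale"]))
        for t, r in doc.get("rescale", {}).items()
    }
    return ContextDatabase(
        window=int(doc["window"]),
        intrinsic=intrinsic,
        pair_terms=pair_terms,
        rescale=rescale,
        config=config,
        version=doc["version"],
    )


__all__ = [
    "DB_VERSION",
    "PROTONATED",
    "DEPROTONATED",
    "ContextDatabase",
    "SiteDeltaTable",
    "load_model_pkas",
    "delta_E",
    "microstate_free_energy",
    "site_delta_tables",
    "generate_synthetic_db",
    "save_db",
    "load_db",
]
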