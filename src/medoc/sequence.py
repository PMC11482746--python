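"""Sequence parsing and q-canonical bookkeeping for charge microstates.

A protein with N ionizable residues populates 2**N charge microstates: every
titratable sidechain is either protonated (state 0) or has released its proton
(state 1).  Microstates sharing a released-proton count — equivalently a net
charge — form a *mesostate*; there are exactly N + 1 mesostates and global
titration experiments report on one free energy per mesostate.

Conventions used throughout the package:

* state 1 means "deprotonated" (proton released to solution);
* each deprotonation lowers the net charge by exactly one elementary charge
  (acids 0 -> -1, bases +1 -> 0);
* the fully protonated microstate is the free-energy reference, G = 0;
* in microstate labels a residue is written uppercase when it is *charged*
  in that state and lowercase when neutral ("e" = protonated Glu, "E" =
  deprotonated Glu, "K" = protonated Lys, "k" = deprotonated Lys);
* positions are 0-based internally, 1-based in all user-facing output.

Arginine is never treated as titratable: its guanidinium group keeps its
proton over the entire experimentally relevant pH range, so it contributes a
fixed +1 charge instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import SequenceError

#: The 20 canonical one-letter amino-acid codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Pseudo-residue type codes for the chain termini (optional titratable sites).
NTERM = "nt"
CTERM = "ct"

ACID = "acid"
BASE = "base"


@dataclass(frozen=True)
class IonizationConfig:
    """Which residues titrate and which carry fixed charges.

    ``acids`` deprotonate 0 -> -1, ``bases`` deprotonate +1 -> 0.  Residues in
    ``fixed_charges`` never titrate but contribute to the net charge (Arg by
    default).  ``include_termini`` adds the alpha-amino and alpha-carboxyl
    groups as pseudo-sites at positions -1 and len(sequence).
    """

    acids: frozenset = frozenset("DECY")
    bases: frozenset = frozenset("HK")
    include_termini: bool = False
    fixed_charges: dict = field(default_factory=lambda: {"R": 1})

    def __post_init__(self):
        overlap = self.acids & self.bases
        if overlap:
            raise SequenceError(f"residue types in both acid and base sets: {sorted(overlap)}")
        if "R" in self.acids or "R" in self.bases:
            raise SequenceError("arginine cannot be configured as a titratable site")

    @property
    def ionizable(self) -> frozenset:
        return self.acids | self.bases


DEFAULT_CONFIG = IonizationConfig()


@dataclass(frozen=True)
class IonizableSite:
    """One titratable group: a sidechain or, optionally, a chain terminus."""

    position: int  # 0-based; -1 for the N-terminus, len(seq) for the C-terminus
    residue_type: str  # one-letter code, or "nt"/"ct" for termini
    klass: str  # "acid" or "base"
    charge_protonated: int
    charge_deprotonated: int

    def __post_init__(self):
        if self.charge_deprotonated != self.charge_protonated - 1:
            raise SequenceError(
                f"site at position {self.position}: deprotonation must lower the "
                f"charge by exactly 1 (got {self.charge_protonated} -> {self.charge_deprotonated})"
            )

    def charge(self, state: int) -> int:
        return self.charge_deprotonated if state else self.charge_protonated


@dataclass(frozen=True)
class SequenceRecord:
    """A parsed sequence with its ordered ionizable sites and charge limits."""

    id: str
    residues: str
    sites: tuple
    config: IonizationConfig = DEFAULT_CONFIG

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def q_max(self) -> int:
        """Net charge of the fully protonated state."""
        q = sum(s.charge_protonated for s in self.sites)
        q += sum(
            self.config.fixed_charges.get(aa, 0)
            for i, aa in enumerate(self.residues)
            if not self._is_site_position(i)
        )
        return q

    @property
    def q_min(self) -> int:
        """Net charge of the fully deprotonated state (q_max - N)."""
        return self.q_max - self.n_sites

    def _is_site_position(self, position: int) -> bool:
        return any(s.position == position for s in self.sites)

    def site_at(self, position: int):
        for i, s in enumerate(self.sites):
            if s.position == position:
                return i, s
        return None

    def net_charge(self, n_released: int) -> int:
        return self.q_max - n_released


@dataclass(frozen=True)
class ChargeMicrostate:
    """One assignment of protonation states with its standard free energy."""

    states: tuple
    n_released: int
    net_charge: int
    label: str
    G_standard: float


@dataclass(frozen=True)
class Mesostate:
    """All microstates sharing a released-proton count, aggregated by F."""

    n_released: int
    net_charge: int
    G: float


def parse_sequence(
    id: str, residues: str, config: IonizationConfig = DEFAULT_CONFIG
) -> SequenceRecord:
    """Parse a one-letter sequence into a :class:`SequenceRecord`.

    Input is case-insensitive.  Unknown letters are rejected with their
    1-based position; empty sequences are rejected.
    """
    seq = residues.strip().upper()
    if not seq:
        raise SequenceError(f"record {id!r}: empty sequence")
    for i, aa in enumerate(seq):
        if aa not in AA_ALPHABET:
            raise SequenceError(
                f"record {id!r}: unknown residue letter {aa!r} at position {i + 1}"
            )
    sites = []
    if config.include_termini:
        sites.append(IonizableSite(-1, NTERM, BASE, 1, 0))
    for i, aa in enumerate(seq):
        if aa in config.acids:
            sites.append(IonizableSite(i, aa, ACID, 0, -1))
        elif aa in config.bases:
            sites.append(IonizableSite(i, aa, BASE, 1, 0))
    if config.include_termini:
        sites.append(IonizableSite(len(seq), CTERM, ACID, 0, -1))
    sites.sort(key=lambda s: s.position)
    return SequenceRecord(id=id, residues=seq, sites=tuple(sites), config=config)


def count_microstates(record: SequenceRecord) -> int:
    """Number of charge microstates, 2**N (1 for a sequence with no sites)."""
    return 2 ** record.n_sites


def enumerate_mesostate_sizes(record: SequenceRecord) -> list:
    """Binomial mesostate sizes [C(N,0), ..., C(N,N)]; sums to 2**N."""
    n = record.n_sites
    return [math.comb(n, k) for k in range(n + 1)]


def _check_states(record: SequenceRecord, states: Sequence[int]) -> tuple:
    states = tuple(int(s) for s in states)
    if len(states) != record.n_sites:
        raise SequenceError(
            f"state vector length {len(states)} != number of sites {record.n_sites}"
        )
    if any(s not in (0, 1) for s in states):
        raise SequenceError("state vector entries must be 0 or 1")
    return states


def microstate_label(record: SequenceRecord, states: Sequence[int]) -> str:
    """Render a microstate as a case-coded string.

    A titratable residue is uppercase when charged in the given state and
    lowercase when neutral; all other residues are rendered uppercase.
    Terminus pseudo-sites have no character in the sequence string and are
    not supported here.
    """
    states = _check_states(record, states)
    chars = list(record.residues)
    for site, s in zip(record.sites, states):
        if site.position < 0 or site.position >= len(chars):
            raise SequenceError("microstate labels are undefined for terminus pseudo-sites")
        aa = site.residue_type
        chars[site.position] = aa.upper() if site.charge(s) != 0 else aa.lower()
    return "".join(chars)


def label_to_states(record: SequenceRecord, label: str) -> tuple:
    """Invert :func:`microstate_label`; the round trip is lossless."""
    if len(label) != len(record.residues):
        raise SequenceError("label length does not match the sequence")
    states = []
    for site in record.sites:
        if site.position < 0 or site.position >= len(label):
            raise SequenceError("microstate labels are undefined for terminus pseudo-sites")
        ch = label[site.position]
        if ch.upper() != site.residue_type.upper():
            raise SequenceError(
                f"label residue {ch!r} at position {site.position + 1} does not match "
                f"site type {site.residue_type!r}"
            )
        charged = ch.isupper()
        # charged <=> the state whose charge is nonzero
        state = 1 if (site.charge(1) != 0) == charged else 0
        states.append(state)
    return tuple(states)


def make_microstate(
    record: SequenceRecord, states: Sequence[int], G_standard: float
) -> ChargeMicrostate:
    states = _check_states(record, states)
    n_rel = sum(states)
    return ChargeMicrostate(
        states=states,
        n_released=n_rel,
        net_charge=record.q_max - n_rel,
        label=microstate_label(record, states),
        G_standard=G_standard,
    )


def read_fasta(
    path, config: IonizationConfig = DEFAULT_CONFIG
) -> list:
    """Read a (possibly multi-record, wrapped) FASTA file into records.

    A trailing ``*`` stop codon is stripped with a warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq.endswith("*"):
            warnings.warn(f"record {rec.id!r}: stripping trailing '*' stop codon")
            seq = seq.rstrip("*")
        records.append(parse_sequence(rec.id, seq, config))
    return records


def sites_table(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Site report with 1-based positions, one row per ionizable site."""
    rows = [
        {
            "id": rec.id,
            "position": site.position + 1,
            "residue": site.residue_type,
            "class": site.klass,
            "charge_protonated": site.charge_protonated,
        }
        for rec in records
        for site in rec.sites
    ]
    return pd.DataFrame(rows, columns=["id", "position", "residue", "class", "charge_protonated"])


def with_config(record: SequenceRecord, config: IonizationConfig) -> SequenceRecord:
    """Re-parse a record under a different ionization configuration."""
    return parse_sequence(record.id, record.residues, config)


__all__ = [
    "AA_ALPHABET",
    "NTERM",
    "CTERM",
    "ACID",
    "BASE",
    "IonizationConfig",
    "DEFAULT_CONFIG",
    "IonizableSite",
    "SequenceRecord",
    "ChargeMicrostate",
    "Mesostate",
    "parse_sequence",
    "count_microstates",
    "enumerate_mesostate_sizes",
    "microstate_label",
    "label_to_states",
    "make_microstate",
    "read_fasta",
    "sites_table",
    "with_config",
]
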