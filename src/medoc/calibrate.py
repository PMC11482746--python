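"""Per-residue-type rescaling of the context database against reference pKa values.

Two knobs per titratable residue type bring a database into agreement with a
set of measured site-specific pKa values: an additive ``intrinsic_offset``
(kcal/mol, shifts the intrinsic deprotonation free energy) and a
multiplicative ``electrostatic_scale`` (dimensionless, scales the summed
neighbor pair terms).  The fit minimizes the RMSD between predicted apparent
pKa values and the targets by deterministic alternating 1-D line searches —
for each type, offset then scale — repeated until the RMSD improves by less
than ``tol`` between sweeps.  A parameter update is kept only if it actually
improves the objective, so parameters with no influence on the targets (e.g.
the scale of an isolated site) stay at their starting values.

Targets whose predicted curve never crosses half-protonation within the pH
grid are flagged and excluded from the objective with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .database import ContextDatabase
from .errors import DatabaseError, SequenceError
from .sequence import SequenceRecord
from .thermo import DEFAULT_THERMO, ThermoParams
from .titration import DEFAULT_PH_GRID, apparent_pKa, site_curves
from .engine import site_mesostate_free_energies

#: (record, 0-based residue position, target pKa)
Reference = Tuple[SequenceRecord, int, float]


@dataclass
class CalibrationReport:
    rmsd: float
    n_used: int
    n_flagged: int
    sweeps: int
    rescale: dict


def _site_index(record: SequenceRecord, position: int) -> int:
    hit = record.site_at(position)
    if hit is None:
        raise SequenceError(
            f"record {record.id!r}: position {position + 1} is not an ionizable site"
        )
    return hit[0]


def _predict_pkas(db, entries, pH_grid, thermo):
    """Predicted apparent pKa per entry (nan where no crossing exists)."""
    out = np.full(len(entries), np.nan)
    by_record: dict = {}
    for j, (record, site_idx, _) in enumerate(entries):
        by_record.setdefault(id(record), (record, []))[1].append((j, site_idx))
    for record, wanted in by_record.values():
        res = site_mesostate_free_energies(db, record, thermo)
        fractions = site_curves(res, pH_grid, thermo)
        for j, site_idx in wanted:
            pka = apparent_pKa(fractions[site_idx], pH_grid)
            if pka.found:
                out[j] = pka.value
    return out


def calibrate_rescaling(
    db: ContextDatabase,
    reference: Sequence[Reference],
    thermo: ThermoParams = DEFAULT_THERMO,
    pH_grid=DEFAULT_PH_GRID,
    tol: float = 1e-4,
    max_sweeps: int = 25,
    offset_halfwidth: float = 4.0,
    scale_bounds: Tuple[float, float] = (0.2, 5.0),
) -> Tuple[ContextDatabase, CalibrationReport]:
    """Fit per-type (intrinsic_offset, electrostatic_scale); returns (db, report)."""
    if not reference:
        raise DatabaseError("calibration requires at least one reference pKa")
    entries = [(rec, _site_index(rec, pos), float(t)) for rec, pos, t in reference]
    targets = np.array([t for _, _, t in entries])
    types = sorted({rec.sites[i].residue_type for rec, i, _ in entries})

    rescale = {t: list(db.rescale_for(t)) for t in types}

    def objective(current_rescale) -> Tuple[float, np.ndarray]:
        trial = db.with_rescale(
            {**dict(db.rescale), **{t: tuple(v) for t, v in current_rescale.items()}}
        )
        pred = _predict_pkas(trial, entries, pH_grid, thermo)
        ok = np.isfinite(pred)
        if not ok.any():
            return math.inf, ok
        return float(np.sqrt(np.mean((pred[ok] - targets[ok]) ** 2))), ok

    rmsd, ok = objective(rescale)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        prev = rmsd
        for t in types:
            for param in (0, 1):  # 0: intrinsic offset, 1: electrostatic scale
                cur = rescale[t][param]
                if param == 0:
                    lo, hi = cur - offset_halfwidth, cur + offset_halfwidth
                else:
                    lo, hi = scale_bounds

                def f(x):
                    rescale[t][param] = x
                    val, _ = objective(rescale)
                    return val

                res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-6})
                # keep the update only if it strictly improves the fit
                if res.fun < rmsd - 1e-12:
                    rescale[t][param] = float(res.x)
                    rmsd = float(res.fun)
                else:
                    rescale[t][param] = cur
        if prev - rmsd < tol:
            break
    final = db.with_rescale(
        {**dict(db.rescale), **{t: tuple(v) for t, v in rescale.items()}}
    )
    rmsd, ok = objective(rescale)
    n_flagged = int((~ok).sum())
    if n_flagged:
        flagged = [
            f"{rec.id}:{rec.sites[i].position + 1}"
            for (rec, i, _), good in zip(entries, ok)
            if not good
        ]
        warnings.warn(
            f"{n_flagged} calibration target(s) have no half-protonation crossing "
            f"in the pH range and were excluded: {flagged}"
        )
    report = CalibrationReport(
        rmsd=rmsd,
        n_used=int(ok.sum()),
        n_flagged=n_flagged,
        sweeps=sweeps,
        rescale={t: tuple(v) for t, v in rescale.items()},
    )
    return final, report


__all__ = ["Reference", "CalibrationReport", "calibrate_rescaling"]
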