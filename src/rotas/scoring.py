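"""Total potential energy of a protein model under trained tables.

Sums, over all heavy-atom pairs within the interaction cutoff (10 A by
default), the distance term (any inter-residue pair) and the angular terms
(pairs at sequence separation >= 6 with both local frames defined).  Angular
energies are rotamer-conditioned table lookups with linear interpolation on
the angle grid; atoms whose rotameric state is undefined, or states never
observed in training, fall back to the state-pooled tables.  Rotamer
intrinsic energies are not included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import pair_geometry, residue_frames
from .potential import POOLED, BuilderConfig, PotentialTables, _typed_atoms
from .rotamers import assign_state, chi_angles
from .structure import StructureModel, read_pdb, sequence_separation

__all__ = ["ScoreBreakdown", "score", "score_batch", "UnscoreableModelError"]


class UnscoreableModelError(ValueError):
    """Model yields no scoreable atom pairs."""


@dataclass
class ScoreBreakdown:
    total: float = 0.0
    e_dist: float = 0.0
    e_theta_i: float = 0.0
    e_phi_i: float = 0.0
    e_theta_j: float = 0.0
    e_phi_j: float = 0.0
    e_omega: float = 0.0
    n_pairs: int = 0
    n_angular_pairs: int = 0
    diagnostics: dict = field(default_factory=dict)

    def _update_total(self):
        self.total = (self.e_dist + self.e_theta_i + self.e_phi_i
                      + self.e_theta_j + self.e_phi_j + self.e_omega)


def _interp(grid: np.ndarray, values: np.ndarray, angle: float) -> float:
    return float(np.interp(angle, grid, values))


def _angular_lookup(angular, key, state, term, grid, angle):
    """Energy of one angular term with pooled fallback; 0 when the pair/bin
    was never observed in training."""
    entry = angular.get(key)
    if entry is None:
        return 0.0
    grids = entry.get(state if state is not None else POOLED)
    if grids is None or term not in grids:
        grids = entry.get(POOLED)
    if grids is None or term not in grids:
        return 0.0
    return _interp(grid, grids[term], angle)


def score(model: StructureModel, tables: PotentialTables,
          cutoff: float | None = None) -> ScoreBreakdown:
    """Evaluate the total energy of one model (deterministic)."""
    cfg: BuilderConfig = tables.config
    cutoff = cfg.score_cutoff if cutoff is None else float(cutoff)
    scheme = cfg.scheme()
    pos, types, res_ord, owners = _typed_atoms(model)
    if len(pos) < 2:
        raise UnscoreableModelError(f"{model.identifier}: fewer than two atoms")
    sep_info = sequence_separation(model)

    frames, states = {}, {}
    res_cache: dict[int, tuple] = {}
    missing_frames = 0
    undefined_states = 0
    for idx, (res, name) in enumerate(owners):
        r_idx = res_ord[idx]
        if r_idx not in res_cache:
            res_cache[r_idx] = (residue_frames(res), chi_angles(res))
        rframes, chis = res_cache[r_idx]
        frames[idx] = rframes.get(name)
        if frames[idx] is None:
            missing_frames += 1
        st = assign_state(res, name, scheme, chis)
        if st.defined:
            states[idx] = st.state_index
        else:
            states[idx] = None
            undefined_states += 1

    tgrid, pgrid = cfg.theta_grid, cfg.phi_grid
    out = ScoreBreakdown()
    out.diagnostics = {"missing_frames": missing_frames,
                       "undefined_states": undefined_states,
                       "skipped_angular_pairs": 0}
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    for a, b in pairs:
        ra, rb = int(res_ord[a]), int(res_ord[b])
        if ra == rb:
            continue
        d = float(np.linalg.norm(pos[a] - pos[b]))
        if d >= cutoff:
            continue
        bin_idx = int(d / cfg.distance_bin_width)
        ti, tj = int(types[a]), int(types[b])
        if tables.dist_usable[ti, tj]:
            out.e_dist += float(tables.e_dist[ti, tj, bin_idx])
        out.n_pairs += 1

        ca, sa, pa = sep_info[ra]
        cb, sb, pb = sep_info[rb]
        if ca == cb and sa == sb and abs(pa - pb) < cfg.min_seq_sep:
            continue
        if d < cfg.angular_min:
            continue
        fa, fb = frames[a], frames[b]
        if fa is None or fb is None:
            out.diagnostics["skipped_angular_pairs"] += 1
            continue
        geom = pair_geometry(fa, fb)
        key_ij = (ti, tj, bin_idx)
        key_ji = (tj, ti, bin_idx)
        ang = tables.angular
        out.e_theta_i += _angular_lookup(ang, key_ij, states[a], "theta",
                                         tgrid, geom.theta_i)
        out.e_phi_i += _angular_lookup(ang, key_ij, states[a], "phi",
                                       pgrid, geom.phi_i)
        out.e_theta_j += _angular_lookup(ang, key_ji, states[b], "theta",
                                         tgrid, geom.theta_j)
        out.e_phi_j += _angular_lookup(ang, key_ji, states[b], "phi",
                                       pgrid, geom.phi_j)
        if geom.omega_defined:
            out.e_omega += (
                _angular_lookup(ang, key_ij, states[a], "omega", tgrid, geom.omega)
                + _angular_lookup(ang, key_ji, states[b], "omega", tgrid, geom.omega)
                - _angular_lookup(ang, key_ij, None, "omega", tgrid, geom.omega)
            )
        out.n_angular_pairs += 1
    if out.n_pairs == 0:
        raise UnscoreableModelError(f"{model.identifier}: no scoreable pairs")
    out._update_total()
    return out


def score_batch(models, tables: PotentialTables,
                cutoff: float | None = None) -> pd.DataFrame:
    """Score a sequence of models or PDB paths; per-model failures are
    reported in the 'error' column rather than raised."""
    rows = []
    for item in models:
        model_id = getattr(item, "identifier", str(item))
        try:
            model = item if isinstance(item, StructureModel) else read_pdb(item)
            bd = score(model, tables, cutoff=cutoff)
            rows.append({
                "model_id": model.identifier, "E_total": bd.total,
                "E_dist": bd.e_dist,
                "E_theta": bd.e_theta_i + bd.e_theta_j,
                "E_phi": bd.e_phi_i + bd.e_phi_j,
                "E_omega": bd.e_omega, "n_pairs": bd.n_pairs,
                "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - resumable batch contract
            rows.append({"model_id": model_id, "E_total": np.nan,
                         "E_dist": np.nan, "E_theta": np.nan,
                         "E_phi": np.nan, "E_omega": np.nan,
                         "n_pairs": 0, "error": str(exc)})
    columns = ["model_id", "E_total", "E_dist", "E_theta", "E_phi",
               "E_omega", "n_pairs", "error"]
    return pd.DataFrame(rows, columns=columns)
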