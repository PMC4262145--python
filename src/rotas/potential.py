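"""Training of the potential: observed statistics to energy tables.

The potential has two parts, both obtained by an inverse-Boltzmann
conversion E = -kT ln(P_obs / P_exp):

* a rotamer-independent distance term over 0.5 A bins in [0, 15) A with the
  DFIRE finite-ideal-gas reference, where expected pair counts grow as
  d**alpha (alpha = 1.61) and observed and expected distributions are tied
  together at the 14.5-15 A cutoff bin;

* rotamer-conditioned angular terms for theta, phi (each endpoint's frame)
  and the inter-frame torsion omega, over 0.5 A bins in [2, 15) A.  Angular
  densities are von Mises kernel density estimates (kappa = 8.21, the
  concentration matching a normal sigma of pi/9) evaluated on a pi/9 grid.
  Sparse rotameric states are shrunk towards the state-pooled density with
  weight w = sigma*N / (1 + sigma*N) (equal weights at N = 1/sigma = 100).
  The reference density is that of a uniformly random relative orientation
  smoothed with the same kernel: uniform for theta and omega, and a
  numerically normalized smoothed cosine for the elevation phi.

The joint omega energy over both endpoint states uses the factorization
P(w|d,Ri,Rj) ~ P(w|d,Ri) P(w|d,Rj) / P(w|d), i.e. the omega energy is
E(w|d,Ri) + E(w|d,Rj) - E(w|d).
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import i0 as bessel_i0

from .geometry import pair_geometry, residue_frames
from .rotamers import RotamerScheme, assign_state, chi_angles, default_scheme
from .structure import (
    StructureModel,
    default_type_table,
    sequence_separation,
)

__all__ = [
    "BuilderConfig",
    "DistanceCounts",
    "AngularSamples",
    "PotentialTables",
    "accumulate_distance",
    "accumulate_angular",
    "dfire_energy",
    "kde_density",
    "corrected_density",
    "expected_angular_density",
    "build",
    "deviation_profile",
    "kappa_from_sigma",
    "save",
    "load",
    "PotentialFormatError",
]

FORMAT_VERSION = "rotas-tables-1"


def kappa_from_sigma(sigma: float) -> float:
    """Von Mises concentration matching a normal kernel of width sigma.

    For concentrated circular data the von Mises distribution approaches a
    wrapped normal with variance 1/kappa, so a linear-kernel bandwidth sigma
    corresponds to kappa = 1/sigma**2 (sigma = pi/9 gives the default 8.21).
    """
    return 1.0 / float(sigma) ** 2

N_TYPES = 167
POOLED = -1  # state key for the rotamer-pooled record


@dataclass(frozen=True)
class BuilderConfig:
    """Parameters of the potential; defaults are the published conditions."""

    distance_bin_width: float = 0.5   # A
    distance_max: float = 15.0        # A; cutoff bin is [14.5, 15)
    angular_min: float = 2.0          # A; angular statistics span [2, 15)
    alpha: float = 1.61               # DFIRE exponent
    kappa: float = 8.21               # von Mises concentration (~ sigma pi/9)
    sigma_mix: float = 0.01           # sparse-state correction rate (1/100)
    min_seq_sep: int = 6              # residues, inclusive threshold
    score_cutoff: float = 10.0        # A, scoring-time interaction cutoff
    grid_step: float = np.pi / 9
    kT: float = 1.0                   # energy scale (dimensionless scores)
    zero_count_energy: float = 10.0   # kT cap for unobserved distance bins
    pro_three_state: bool = False

    def __post_init__(self):
        n = (2 * np.pi) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid_step must divide the circle evenly")

    @property
    def n_bins(self) -> int:
        return int(round(self.distance_max / self.distance_bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        w = self.distance_bin_width
        return w / 2 + w * np.arange(self.n_bins)

    @property
    def first_angular_bin(self) -> int:
        return int(self.angular_min / self.distance_bin_width)

    @property
    def theta_grid(self) -> np.ndarray:
        n = int(round(2 * np.pi / self.grid_step))
        return np.linspace(-np.pi, np.pi, n + 1)

    @property
    def phi_grid(self) -> np.ndarray:
        n = int(round(np.pi / self.grid_step))
        return np.linspace(-np.pi / 2, np.pi / 2, n + 1)

    def scheme(self) -> RotamerScheme:
        if self.pro_three_state:
            return RotamerScheme(pro_three_state=True)
        return default_scheme()


# ----------------------------------------------------------------- counting

class DistanceCounts:
    """Pair counts N_obs(type_i, type_j, bin); one count per unordered pair,
    stored under the sorted type key."""

    def __init__(self, config: BuilderConfig):
        self.config = config
        self.counts = np.zeros((N_TYPES, N_TYPES, config.n_bins), dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def symmetric(self) -> np.ndarray:
        return self.counts + self.counts.swapaxes(0, 1)


def _typed_atoms(model: StructureModel):
    """Flat arrays (positions, type indices, residue ordinals) plus the
    per-atom (residue, atom_name) list, enumeration order of model.atoms()."""
    table = default_type_table()
    pos, types, res_ord, owners = [], [], [], []
    for r_idx, res in enumerate(model.residues()):
        for name, atom in res.atoms.items():
            pos.append(atom.position)
            types.append(table.type_of(res.residue_name, name))
            res_ord.append(r_idx)
            owners.append((res, name))
    if not pos:
        return np.empty((0, 3)), np.empty(0, int), np.empty(0, int), []
    return np.asarray(pos), np.asarray(types), np.asarray(res_ord), owners


def accumulate_distance(model: StructureModel, counts: DistanceCounts) -> DistanceCounts:
    """Count all unordered inter-residue heavy-atom pairs below the cutoff.

    No sequence-separation filter applies to the distance term; only
    same-residue pairs are excluded.
    """
    cfg = counts.config
    pos, types, res_ord, _ = _typed_atoms(model)
    if len(pos) < 2:
        return counts
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cfg.distance_max, output_type="ndarray")
    if len(pairs) == 0:
        return counts
    a, b = pairs[:, 0], pairs[:, 1]
    keep = res_ord[a] != res_ord[b]
    a, b = a[keep], b[keep]
    d = np.linalg.norm(pos[a] - pos[b], axis=1)
    keep = d < cfg.distance_max
    a, b, d = a[keep], b[keep], d[keep]
    bins = (d / cfg.distance_bin_width).astype(int)
    ti = np.minimum(types[a], types[b])
    tj = np.maximum(types[a], types[b])
    np.add.at(counts.counts, (ti, tj, bins), 1)
    return counts


class AngularSamples:
    """Streaming kernel sums of the angular observations.

    entries[(ti, tj, bin)][state] -> record with kernel sums on the theta,
    phi and omega grids plus sample counts (omega counted separately because
    a pair whose z-axis is parallel to the inter-atomic axis has no omega).
    Ordered type keys: the record under (ti, tj) describes the angles of the
    type-i endpoint conditioned on its own rotameric state.
    """

    def __init__(self, config: BuilderConfig):
        self.config = config
        self.entries: dict[tuple[int, int, int], dict[int, dict]] = {}
        self._n_theta = len(config.theta_grid)
        self._n_phi = len(config.phi_grid)

    def _record(self, key, state):
        per_state = self.entries.setdefault(key, {})
        rec = per_state.get(state)
        if rec is None:
            rec = {
                "theta": np.zeros(self._n_theta),
                "phi": np.zeros(self._n_phi),
                "omega": np.zeros(self._n_theta),
                "n": 0,
                "n_omega": 0,
            }
            per_state[state] = rec
        return rec

    def add(self, ti, tj, bin_idx, state, theta, phi, omega):
        cfg = self.config
        rec = self._record((ti, tj, bin_idx), state)
        rec["theta"] += np.exp(cfg.kappa * np.cos(cfg.theta_grid - theta))
        rec["phi"] += np.exp(cfg.kappa * np.cos(cfg.phi_grid - phi))
        rec["n"] += 1
        if omega is not None and np.isfinite(omega):
            rec["omega"] += np.exp(cfg.kappa * np.cos(cfg.theta_grid - omega))
            rec["n_omega"] += 1

    def pooled(self, key) -> dict | None:
        per_state = self.entries.get(key)
        if not per_state:
            return None
        out = None
        for rec in per_state.values():
            if out is None:
                out = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                       for k, v in rec.items()}
            else:
                for k, v in rec.items():
                    out[k] = out[k] + v
        return out

    @property
    def n_samples(self) -> int:
        return sum(rec["n"] for per_state in self.entries.values()
                   for rec in per_state.values())


def accumulate_angular(model: StructureModel, samples: AngularSamples) -> AngularSamples:
    """Record angular observations for eligible pairs of one structure.

    Eligible: 2 <= d < 15 A, sequence separation >= 6 within a chain segment
    (cross-chain and cross-break pairs always qualify), both local frames
    defined.  Each unordered pair is recorded in both ordered directions.
    """
    cfg = samples.config
    scheme = cfg.scheme()
    pos, types, res_ord, owners = _typed_atoms(model)
    if len(pos) < 2:
        return samples
    sep_info = sequence_separation(model)

    # per-residue frames and per-atom rotamer states, computed once
    frames, states = {}, {}
    res_cache: dict[int, tuple] = {}
    for idx, (res, name) in enumerate(owners):
        r_idx = res_ord[idx]
        if r_idx not in res_cache:
            res_cache[r_idx] = (residue_frames(res), chi_angles(res))
        rframes, chis = res_cache[r_idx]
        frames[idx] = rframes.get(name)
        st = assign_state(res, name, scheme, chis)
        states[idx] = st.state_index if st.defined else None

    tree = cKDTree(pos)
    pairs = tree.query_pairs(cfg.distance_max, output_type="ndarray")
    for a, b in pairs:
        ra, rb = int(res_ord[a]), int(res_ord[b])
        if ra == rb:
            continue
        ca, sa, pa = sep_info[ra]
        cb, sb, pb = sep_info[rb]
        if ca == cb and sa == sb and abs(pa - pb) < cfg.min_seq_sep:
            continue
        fa, fb = frames[a], frames[b]
        if fa is None or fb is None:
            continue
        geom = pair_geometry(fa, fb)
        if not (cfg.angular_min <= geom.d < cfg.distance_max):
            continue
        bin_idx = int(geom.d / cfg.distance_bin_width)
        omega = geom.omega if geom.omega_defined else None
        st_a = states[a] if states[a] is not None else None
        st_b = states[b] if states[b] is not None else None
        samples.add(int(types[a]), int(types[b]), bin_idx,
                    st_a if st_a is not None else POOLED - 1,
                    geom.theta_i, geom.phi_i, omega)
        # omega is swap-symmetric, so both ordered directions share it
        samples.add(int(types[b]), int(types[a]), bin_idx,
                    st_b if st_b is not None else POOLED - 1,
                    geom.theta_j, geom.phi_j, omega)
    return samples


# ------------------------------------------------------------ density tools

def _trapz(y: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def kde_density(samples, kappa: float, grid: np.ndarray) -> np.ndarray:
    """Mean of von Mises kernels centered at the samples, on the grid,
    renormalized so the trapezoidal integral over the grid span is one."""
    samples = np.atleast_1d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("kde_density requires at least one sample")
    dens = np.exp(kappa * np.cos(grid[:, None] - samples[None, :])).mean(axis=1)
    dens = dens / (2 * np.pi * bessel_i0(kappa))
    return dens / _trapz(dens, grid)


def _density_from_sums(sums: np.ndarray, n: int, kappa: float,
                       grid: np.ndarray) -> np.ndarray:
    dens = sums / (n * 2 * np.pi * bessel_i0(kappa))
    return dens / _trapz(dens, grid)


def corrected_density(p_state: np.ndarray, p_pooled: np.ndarray,
                      n_state: int, sigma_mix: float) -> np.ndarray:
    """Shrink a sparse-state density towards the pooled one:
    w p_state + (1 - w) p_pooled with w = sigma N / (1 + sigma N)."""
    w = sigma_mix * n_state / (1.0 + sigma_mix * n_state)
    return w * p_state + (1.0 - w) * p_pooled


def expected_angular_density(domain: str, kappa: float,
                             grid: np.ndarray) -> np.ndarray:
    """Reference density of a uniformly random relative orientation,
    smoothed with the same kernel as the observations.

    theta and omega are uniform on the circle (smoothing preserves this);
    the elevation phi has prior cos(phi)/2, smoothed and renormalized
    numerically on the grid.
    """
    if domain in ("theta", "omega"):
        return np.full(len(grid), 1.0 / (2 * np.pi))
    if domain != "phi":
        raise ValueError(f"unknown domain {domain!r}")
    fine = np.linspace(-np.pi / 2, np.pi / 2, 2001)
    prior = np.cos(fine) / 2.0
    kernel = np.exp(kappa * np.cos(grid[:, None] - fine[None, :]))
    kernel /= 2 * np.pi * bessel_i0(kappa)
    dens = np.trapezoid(kernel * prior[None, :], fine, axis=1)
    return dens / _trapz(dens, grid)


# ------------------------------------------------------------- energy build

def dfire_energy(counts: DistanceCounts, config: BuilderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Distance energies from pair counts with the DFIRE reference.

    Returns (energy, usable) where usable flags type pairs with a nonzero
    cutoff-bin count; unusable pairs score zero with a warning.  Unobserved
    bins of usable pairs get the capped repulsive energy.
    """
    n = counts.symmetric().astype(float)
    centers = config.bin_centers
    ratio = (centers / centers[-1]) ** config.alpha  # bin widths are equal
    n_cut = n[:, :, -1]
    usable = n_cut > 0
    if not np.all(usable[n.sum(axis=2) > 0]):
        warnings.warn("type pairs without cutoff-bin counts score zero")
    energy = np.full_like(n, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = -config.kT * np.log(n / (ratio[None, None, :] * n_cut[:, :, None]))
    observed = n > 0
    mask = usable[:, :, None] & observed
    energy[mask] = e[mask]
    energy[usable[:, :, None] & ~observed] = config.zero_count_energy * config.kT
    energy[:, :, -1] = np.where(usable, 0.0, energy[:, :, -1])
    return energy, usable


@dataclass
class PotentialTables:
    """Trained energy tables plus provenance metadata.

    ``angular[(ti, tj, bin)]`` maps a state index (or POOLED = -1) to a dict
    of energy grids {"theta": (19,), "phi": (10,), "omega": (19,)}; omega
    grids may be absent when no omega sample existed.
    """

    config: BuilderConfig
    e_dist: np.ndarray
    dist_usable: np.ndarray
    angular: dict[tuple[int, int, int], dict[int, dict[str, np.ndarray]]]
    metadata: dict = field(default_factory=dict)


def _angular_energies(samples: AngularSamples) -> dict:
    cfg = samples.config
    tgrid, pgrid = cfg.theta_grid, cfg.phi_grid
    exp_theta = expected_angular_density("theta", cfg.kappa, tgrid)
    exp_phi = expected_angular_density("phi", cfg.kappa, pgrid)
    exp_omega = expected_angular_density("omega", cfg.kappa, tgrid)
    out: dict = {}
    for key, per_state in samples.entries.items():
        pooled = samples.pooled(key)
        if pooled is None or pooled["n"] == 0:
            continue
        p_th_pool = _density_from_sums(pooled["theta"], pooled["n"], cfg.kappa, tgrid)
        p_ph_pool = _density_from_sums(pooled["phi"], pooled["n"], cfg.kappa, pgrid)
        entry: dict[int, dict[str, np.ndarray]] = {}
        pooled_entry = {
            "theta": -cfg.kT * np.log(p_th_pool / exp_theta),
            "phi": -cfg.kT * np.log(p_ph_pool / exp_phi),
        }
        p_om_pool = None
        if pooled["n_omega"] > 0:
            p_om_pool = _density_from_sums(pooled["omega"], pooled["n_omega"],
                                           cfg.kappa, tgrid)
            pooled_entry["omega"] = -cfg.kT * np.log(p_om_pool / exp_omega)
        entry[POOLED] = pooled_entry
        for state, rec in per_state.items():
            if state < 0 or rec["n"] == 0:
                continue  # undefined-state bucket feeds only the pooled table
            p_th = _density_from_sums(rec["theta"], rec["n"], cfg.kappa, tgrid)
            p_ph = _density_from_sums(rec["phi"], rec["n"], cfg.kappa, pgrid)
            p_th = corrected_density(p_th, p_th_pool, rec["n"], cfg.sigma_mix)
            p_ph = corrected_density(p_ph, p_ph_pool, rec["n"], cfg.sigma_mix)
            st_entry = {
                "theta": -cfg.kT * np.log(p_th / exp_theta),
                "phi": -cfg.kT * np.log(p_ph / exp_phi),
            }
            if rec["n_omega"] > 0 and p_om_pool is not None:
                p_om = _density_from_sums(rec["omega"], rec["n_omega"],
                                          cfg.kappa, tgrid)
                p_om = corrected_density(p_om, p_om_pool, rec["n_omega"],
                                         cfg.sigma_mix)
                st_entry["omega"] = -cfg.kT * np.log(p_om / exp_omega)
            entry[state] = st_entry
        out[key] = entry
    return out


def build(models, config: BuilderConfig | None = None,
          manifest: list[str] | None = None) -> PotentialTables:
    """Train the full potential on an iterable of StructureModel."""
    config = config or BuilderConfig()
    models = list(models)
    if not models:
        raise ValueError("empty training set")
    counts = DistanceCounts(config)
    samples = AngularSamples(config)
    for model in models:
        accumulate_distance(model, counts)
        accumulate_angular(model, samples)
    e_dist, usable = dfire_energy(counts, config)
    angular = _angular_energies(samples)
    meta = {
        "format_version": FORMAT_VERSION,
        "typing_checksum": default_type_table().checksum(),
        "training_manifest": manifest or [m.identifier for m in models],
        "n_structures": len(models),
        "n_distance_pairs": counts.total,
        "n_angular_samples": samples.n_samples,
    }
    return PotentialTables(config, e_dist, usable, angular, meta)


def deviation_profile(samples: AngularSamples) -> pd.DataFrame:
    """RMS of (P_obs - P_exp) per distance bin for each angular parameter,
    with observations pooled over all atom-type pairs (diagnostic)."""
    cfg = samples.config
    grids = {"theta": cfg.theta_grid, "phi": cfg.phi_grid,
             "omega": cfg.theta_grid}
    expected = {name: expected_angular_density(name, cfg.kappa, grid)
                for name, grid in grids.items()}
    merged: dict[int, dict] = {}
    for (ti, tj, bin_idx), _ in samples.entries.items():
        pooled = samples.pooled((ti, tj, bin_idx))
        agg = merged.setdefault(bin_idx, {
            "theta": np.zeros(len(cfg.theta_grid)),
            "phi": np.zeros(len(cfg.phi_grid)),
            "omega": np.zeros(len(cfg.theta_grid)),
            "n": 0, "n_omega": 0,
        })
        for k in ("theta", "phi", "omega", "n", "n_omega"):
            agg[k] = agg[k] + pooled[k]
    rows = []
    for bin_idx in range(cfg.first_angular_bin, cfg.n_bins):
        agg = merged.get(bin_idx)
        for name, grid in grids.items():
            n = 0 if agg is None else (agg["n_omega"] if name == "omega" else agg["n"])
            if n > 0:
                p_obs = _density_from_sums(agg[name], n, cfg.kappa, grid)
                rms = float(np.sqrt(np.mean((p_obs - expected[name]) ** 2)))
            else:
                rms = np.nan
            rows.append({"bin": bin_idx,
                         "distance": cfg.bin_centers[bin_idx],
                         "angle": name, "rms": rms, "n": int(n)})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- persistence

class PotentialFormatError(ValueError):
    """Unreadable, truncated or incompatible potential archive."""


def save(tables: PotentialTables, path: str | Path) -> None:
    """Write the tables as a .npz archive with a JSON metadata entry."""
    keys, th, ph, om, has_om = [], [], [], [], []
    for (ti, tj, b), per_state in tables.angular.items():
        for state, grids in per_state.items():
            keys.append((ti, tj, b, state))
            th.append(grids["theta"])
            ph.append(grids["phi"])
            omega = grids.get("omega")
            has_om.append(omega is not None)
            om.append(omega if omega is not None
                      else np.zeros_like(grids["theta"]))
    meta = dict(tables.metadata)
    meta["config"] = asdict(tables.config)
    np.savez_compressed(
        Path(path),
        meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        e_dist=tables.e_dist,
        dist_usable=tables.dist_usable,
        ang_keys=np.asarray(keys, dtype=np.int64).reshape(-1, 4),
        ang_theta=np.asarray(th).reshape(-1, len(tables.config.theta_grid)),
        ang_phi=np.asarray(ph).reshape(-1, len(tables.config.phi_grid)),
        ang_omega=np.asarray(om).reshape(-1, len(tables.config.theta_grid)),
        ang_has_omega=np.asarray(has_om, dtype=bool),
    )


def load(path: str | Path) -> PotentialTables:
    """Read a potential archive; validates version and typing checksum."""
    try:
        with np.load(Path(path)) as data:
            arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise PotentialFormatError(f"unreadable potential archive: {exc}") from exc
    try:
        meta = json.loads(bytes(arrays["meta"]).decode())
        cfg_dict = meta.pop("config")
        config = BuilderConfig(**cfg_dict)
        angular: dict = {}
        for (ti, tj, b, state), th, ph, om, has_om in zip(
            arrays["ang_keys"], arrays["ang_theta"], arrays["ang_phi"],
            arrays["ang_omega"], arrays["ang_has_omega"],
        ):
            entry = angular.setdefault((int(ti), int(tj), int(b)), {})
            grids = {"theta": th, "phi": ph}
            if has_om:
                grids["omega"] = om
            entry[int(state)] = grids
        tables = PotentialTables(config, arrays["e_dist"],
                                 arrays["dist_usable"], angular, meta)
    except KeyError as exc:
        raise PotentialFormatError(f"missing entry in archive: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise PotentialFormatError(
            f"format version {meta.get('format_version')!r} != {FORMAT_VERSION!r}"
        )
    if meta.get("typing_checksum") != default_type_table().checksum():
        raise PotentialFormatError("typing-table checksum mismatch")
    return tables
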