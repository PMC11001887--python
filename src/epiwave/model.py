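"""Modified vertex model of follicle-cell expansion waves.

Cells are polygons with many boundary vertices (discrete adhesion clusters)
moving by overdamped force balance::

    eta_vis * dx/dt = F_tension + F_area + F_rac + F_adhesion + F_fiber + F_noise

integrated with an explicit Euler step. The protocol runs three phases —
ruffling (random protrusive pulses, weak adhesion), area increasing and
spreading (anterior-targeted pulses, strong adhesion, substrate advection
by oocyte A-P growth). Ruffling onset propagates as a posterior-to-anterior
wave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .geometry import (
    BoundaryPolygon,
    TissueMesh,
    hexagonal_tiling,
    outward_normal,
    polygon_measures,
)

__all__ = [
    "ModelParams",
    "PhaseProgram",
    "Genotype",
    "GENOTYPES",
    "Simulation",
    "run_protocol",
    "force_tension",
    "force_area",
    "force_rac",
    "force_adhesion",
    "force_fiber",
    "force_noise",
    "apply_oocyte_growth",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ModelParams:
    """All mechanical parameters of the force-balance model.

    Units are a consistent force/length(um)/time(min) system calibrated so
    that the wild-type protocol reproduces the ruffling -> increasing ->
    spreading phenomenology; no absolute force scale is implied.
    """

    eta_vis: float = 1.0          # drag coefficient (force*min/um)
    line_tension: float = 0.05    # K_L (force/um)
    area_stiffness: float = 1.0   # K_a (force/um^3)
    target_area: float | None = None  # A0 (um^2); None -> initial cell areas
    rac_strength: float = 2.5     # f_Rac (force*min)
    rac_sigma: float = 4.0        # sigma of one protrusion cycle (min)
    rac_duration: float = 20.0    # T, duration of one protrusion cycle (min)
    cam_strength: float = 1.0     # f_CAMs (force/um)
    rho_level: float = 1.0        # L_Rho (dimensionless concentration)
    hill_dissociation: float = 1.0  # K_d
    hill_coeff: float = 2.0       # n
    fiber_stiffness: float = 0.5  # K_Fiber (force/um)
    fiber_rest_len: float | None = None  # L0 (um); None -> set at engagement
    noise_strength: float = 0.01  # f_R (force)
    dt: float = 0.05              # integration step (min)
    adhesion_delay: float = 2.0   # adhesion re-engagement delay after Rac onset (min)
    anchor_turnover_time: float = 5.0  # substrate anchor re-seating clock (min)

    def validate(self) -> None:
        positives = [
            "eta_vis", "line_tension", "area_stiffness", "rac_sigma",
            "rac_duration", "hill_dissociation", "dt",
        ]
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hill_coeff < 1:
            raise ValueError("hill_coeff must be >= 1")
        if self.adhesion_delay < 0:
            raise ValueError("adhesion_delay must be >= 0")

    def stability_dt_bound(self) -> float:
        """Explicit-Euler bound dt < eta_vis / k_max for the stiffest
        single-vertex restoring coefficient in play."""
        k_max = (
            4.0 * self.line_tension
            + self.cam_strength
            + self.fiber_stiffness
            + self.area_stiffness
        )
        return self.eta_vis / k_max


@dataclass
class PhaseProgram:
    """Phase schedule: wave-staggered ruffling, then increasing + spreading.

    Ruffling starts per cell at ``wave_t0 + distance_from_posterior /
    wave_speed`` and ends globally at ``wave_t0 + ruffling_duration``; the
    Rho multiplier is low during ruffling and ramps high across the
    increasing window; stress fibers engage (rest length frozen) at the
    ruffling -> increasing transition; oocyte A-P growth also starts there.
    """

    ruffling_duration: float = 60.0
    increasing_duration: float = 20.0
    spreading_duration: float = 80.0
    wave_t0: float = 0.0
    wave_speed: float = 2.0            # um/min, P-to-A; inf -> simultaneous
    rac_arc_fraction: float = 0.25     # boundary fraction hit per ruffling pulse
    anterior_arc_fraction: float = 0.30  # boundary fraction targeted post-ruffling
    anterior_rac_mult: float = 0.3     # pulse strength once targeting turns anterior
    tension_rho_coupling: bool = True  # cortical tension scales with Rho activity
    rho_ruffling_mult: float = 0.3
    rho_high_mult: float = 2.0
    fiber_ruffling_mult: float = 0.0   # fibers disengaged while ruffling
    fiber_engaged_mult: float = 1.0
    growth_rate: float = 0.0035        # g: fractional A-P anchor extension per min
    a0_follows_growth: bool = True     # target area tracks the A-P stretch factor
    n_fibers_per_cell: int = 3

    def validate(self) -> None:
        for name in ("ruffling_duration", "increasing_duration", "spreading_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be > 0 (use inf for simultaneous onset)")
        if not 0 < self.rac_arc_fraction <= 1:
            raise ValueError("rac_arc_fraction must be in (0, 1]")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")

    @property
    def ruffling_end(self) -> float:
        return self.wave_t0 + self.ruffling_duration

    @property
    def total_duration(self) -> float:
        return (
            self.wave_t0
            + self.ruffling_duration
            + self.increasing_duration
            + self.spreading_duration
        )


@dataclass(frozen=True)
class Genotype:
    """Multiplicative perturbation of the wild-type parameter set."""

    name: str
    rac_mult: float = 1.0
    rho_mult: float = 1.0
    cam_mult: float = 1.0
    fiber_mult: float = 1.0
    dumping_mult: float = 1.0  # scales the A-P growth rate in combined mode
    ruffling_duration_override: float | None = None  # combined mode only
    simultaneous_onset: bool = False  # infinite wave speed

    def __post_init__(self):
        for name in ("rac_mult", "rho_mult", "cam_mult", "fiber_mult", "dumping_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


GENOTYPES: dict[str, Genotype] = {
    g.name: g
    for g in [
        Genotype("WT"),
        Genotype("Rac1DN_weak", rac_mult=0.5, dumping_mult=0.75,
                 ruffling_duration_override=40.0),
        Genotype("Rac1DN_strong", rac_mult=0.1, dumping_mult=0.5,
                 ruffling_duration_override=40.0),
        Genotype("Rho1DN", rho_mult=0.3, fiber_mult=0.3, dumping_mult=0.3),
        Genotype("PaxOE", cam_mult=2.0, fiber_mult=1.5, dumping_mult=1.0),
        Genotype("TalinRNAi", cam_mult=0.5, fiber_mult=0.5, dumping_mult=0.7),
        Genotype("DumpingInhibited", dumping_mult=0.05, simultaneous_onset=True),
    ]
}


def get_genotype(name: str | Genotype) -> Genotype:
    if isinstance(name, Genotype):
        return name
    try:
        return GENOTYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown genotype {name!r}; presets: {sorted(GENOTYPES)}"
        ) from None


# ---------------------------------------------------------------------------
# Individual force terms (reference scalar implementations)


def force_tension(vertex, prev_neighbor, next_neighbor, k_l: float) -> np.ndarray:
    """Cortical tension on a vertex: zero-rest-length springs to both
    cortex neighbours, F = K_L * (s+ + s-)."""
    v = np.asarray(vertex, float)
    return k_l * (
        (np.asarray(next_neighbor, float) - v) + (np.asarray(prev_neighbor, float) - v)
    )


def force_area(
    cell: BoundaryPolygon,
    vertex_index: int,
    k_a: float,
    a0: float,
    variant: str = "cortical",
) -> np.ndarray:
    """Area-elasticity force at one vertex of a cell.

    ``variant='cortical'`` reads the covered cortical length as the mean of
    the two adjacent edge lengths, s_hat = (|s+| + |s-|)/2. The
    ``'gradient'`` variant instead uses half the neighbour chord length,
    which makes the force exactly minus the gradient of (K_a/2)(A - A0)^2
    (the two coincide on densely sampled smooth boundaries); the integrator
    uses the gradient form.
    """
    v = cell.vertices
    i = int(vertex_index)
    n = v.shape[0]
    prv, nxt = v[(i - 1) % n], v[(i + 1) % n]
    area = polygon_measures(cell)["area"]
    r_nor = outward_normal(cell, i)
    if variant == "cortical":
        s_hat = 0.5 * (np.linalg.norm(nxt - v[i]) + np.linalg.norm(v[i] - prv))
    elif variant == "gradient":
        s_hat = 0.5 * np.linalg.norm(nxt - prv)
    else:
        raise ValueError("variant must be 'cortical' or 'gradient'")
    return -k_a * s_hat * (area - a0) * r_nor


def force_rac(
    t: float,
    pulse_start: float,
    f_rac: float,
    sigma: float,
    duration: float,
    r_nor,
    active: bool = True,
) -> np.ndarray:
    """Protrusive pulse normal to the membrane.

    Gaussian envelope centred mid-cycle: amplitude
    f_Rac/(sigma*sqrt(2*pi)) * exp(-0.5*((2*tau - T)/(2*sigma))^2)
    for tau = t - pulse_start within [0, T]; zero outside or when inactive.
    """
    if sigma <= 0 or duration <= 0:
        raise ValueError("sigma and duration must be > 0")
    r_nor = np.asarray(r_nor, float)
    tau = t - pulse_start
    if not active or tau < 0 or tau > duration:
        return np.zeros(2)
    z = (2.0 * tau - duration) / (2.0 * sigma)
    mag = f_rac / (sigma * math.sqrt(2.0 * math.pi)) * math.exp(-0.5 * z * z)
    return mag * r_nor


def hill_factor(l_rho: float, k_d: float, n: float) -> float:
    """Hill saturation L_Rho^n / (K_d + L_Rho^n) gating the adhesion force."""
    if l_rho < 0:
        raise ValueError("rho level must be >= 0")
    if k_d <= 0:
        raise ValueError("K_d must be > 0")
    ln = l_rho**n
    return ln / (k_d + ln)


def force_adhesion(
    vertex_pos, anchor_pos, f_cams: float, l_rho: float, k_d: float, n: float
) -> np.ndarray:
    """Hill-gated restoring force toward the substrate anchor."""
    dx = np.asarray(anchor_pos, float) - np.asarray(vertex_pos, float)
    return f_cams * hill_factor(l_rho, k_d, n) * dx


def force_fiber(end_a, end_b, k_fiber: float, rest_len: float):
    """One-sided stress-fiber spring.

    Returns the force pair (on end_a, on end_b). Pulls the endpoints
    together with magnitude K_Fiber*(L - L0) when stretched beyond the
    critical length L0; supports no compression (zero for L <= L0).
    """
    a = np.asarray(end_a, float)
    b = np.asarray(end_b, float)
    d = b - a
    dist = float(np.hypot(*d))
    if dist <= 1e-12:
        raise ValueError("fiber endpoints coincide")
    ext = dist - rest_len
    if ext <= 0:
        z = np.zeros(2)
        return z, z.copy()
    f = k_fiber * ext * d / dist
    return f, -f


def force_noise(f_r: float, rng: np.random.Generator) -> np.ndarray:
    """F = f_R * (g1, g2) with independent standard normals."""
    return f_r * rng.standard_normal(2)


def apply_oocyte_growth(
    anchors: np.ndarray, g: float, dt: float, x_posterior: float
) -> np.ndarray:
    """Advect substrate anchors by oocyte A-P extension.

    A-P coordinates stretch affinely about the posterior edge:
    x <- x_post + (x - x_post) * (1 + g*dt); D-V coordinates are untouched.
    Returns a new array.
    """
    if g < 0:
        raise ValueError("growth rate must be >= 0")
    out = anchors.copy()
    out[:, 0] = x_posterior + (out[:, 0] - x_posterior) * (1.0 + g * dt)
    return out


# ---------------------------------------------------------------------------
# Engine


class Simulation:
    """Vectorised integrator for one tissue patch and one genotype.

    The constructor freezes per-cell ruffling onsets from initial centroid
    distances to the posterior edge. ``step()`` advances one dt; ``run()``
    integrates a duration and records frames.
    """

    def __init__(
        self,
        mesh: TissueMesh,
        params: ModelParams,
        program: PhaseProgram,
        genotype: Genotype | str = "WT",
        mode: str = "combined_factor",
        seed: int = 0,
    ):
        params.validate()
        program.validate()
        if mode not in ("single_factor", "combined_factor"):
            raise ValueError("mode must be 'single_factor' or 'combined_factor'")
        genotype = get_genotype(genotype)
        if genotype.ruffling_duration_override is not None and mode == "combined_factor":
            program = replace(
                program, ruffling_duration=genotype.ruffling_duration_override
            )
        self.mesh = mesh.copy()
        self.params = params
        self.program = program
        self.genotype = genotype
        self.mode = mode
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.t = 0.0

        if params.dt >= params.stability_dt_bound():
            raise ValueError(
                f"dt={params.dt} exceeds the stability bound "
                f"{params.stability_dt_bound():.4g} (= eta_vis / k_max)"
            )

        # flattened loop topology
        loop_idx, nxt_idx, prv_idx, cell_of = [], [], [], []
        self._cell_slices = []
        for ci, loop in enumerate(self.mesh.cells):
            start = len(loop_idx)
            loop_idx.extend(int(i) for i in loop)
            nxt_idx.extend(int(i) for i in np.roll(loop, -1))
            prv_idx.extend(int(i) for i in np.roll(loop, 1))
            cell_of.extend([ci] * len(loop))
            self._cell_slices.append(slice(start, len(loop_idx)))
        self.loop_idx = np.asarray(loop_idx, int)
        self.nxt_idx = np.asarray(nxt_idx, int)
        self.prv_idx = np.asarray(prv_idx, int)
        self.cell_of = np.asarray(cell_of, int)
        self.n_cells = self.mesh.n_cells
        self.n_pool = self.mesh.n_vertices

        # initial morphometrics and phase onsets
        areas0, cx0 = [], []
        for i in range(self.n_cells):
            m = polygon_measures(self.mesh.cell_polygon(i))
            areas0.append(m["area"])
            cx0.append(m["centroid"][0])
        self.area0 = np.asarray(areas0)
        self.a0_init = (
            np.full(self.n_cells, params.target_area)
            if params.target_area is not None
            else self.area0.copy()
        )
        self.centroid_x0 = np.asarray(cx0)
        self.x_posterior = float(self.mesh.vertex_pool[:, 0].max())
        if genotype.simultaneous_onset or not np.isfinite(program.wave_speed):
            self.onset = np.full(self.n_cells, program.wave_t0)
        else:
            dist = self.x_posterior - self.centroid_x0
            self.onset = program.wave_t0 + dist / program.wave_speed

        # oocyte growth rate: single-factor mode pre-sets the WT rate for every
        # genotype except the dumping perturbation itself (dumping IS its factor)
        g_wt = program.growth_rate
        if mode == "combined_factor" or genotype.dumping_mult != 1.0 and (
            genotype.rac_mult == genotype.rho_mult == genotype.cam_mult
            == genotype.fiber_mult == 1.0
        ):
            self.g = g_wt * genotype.dumping_mult
        else:
            self.g = g_wt
        self.growth_start = program.ruffling_end
        self.growth_factor = 1.0

        # Rac pulse state
        self._cycle_index = np.full(self.n_cells, -1, int)
        self._cycle_start = np.full(self.n_cells, -np.inf)
        self._active_entries = np.zeros(self.loop_idx.size, bool)
        self._last_rac_onset = np.full(self.n_pool, -np.inf)

        # fibers (engage at ruffling end)
        self._fibers_engaged = False
        self.fiber_i = np.zeros(0, int)
        self.fiber_j = np.zeros(0, int)
        self.fiber_l0 = np.zeros(0)

        self._last_turnover = 0.0
        self._nan_guard_every = max(1, int(round(1.0 / params.dt)))
        self._steps = 0

    # -- schedules ---------------------------------------------------------

    def rho_multiplier(self, t: float) -> float:
        pr = self.program
        if t < pr.ruffling_end:
            return pr.rho_ruffling_mult
        ramp_end = pr.ruffling_end + pr.increasing_duration
        if t < ramp_end and pr.increasing_duration > 0:
            frac = (t - pr.ruffling_end) / pr.increasing_duration
            return pr.rho_ruffling_mult + frac * (pr.rho_high_mult - pr.rho_ruffling_mult)
        return pr.rho_high_mult

    def _refresh_rac_targets(self) -> None:
        pr, pm = self.program, self.params
        t = self.t
        pos = self.mesh.vertex_pool
        for ci in range(self.n_cells):
            if t < self.onset[ci]:
                continue
            ruffling = t < pr.ruffling_end
            ref = self.onset[ci] if ruffling else pr.ruffling_end
            k = int((t - ref) // pm.rac_duration)
            if k == self._cycle_index[ci] and not (
                ruffling is False and self._cycle_start[ci] < pr.ruffling_end
            ):
                continue
            sl = self._cell_slices[ci]
            loop = self.loop_idx[sl]
            n = loop.size
            mask = np.zeros(n, bool)
            if ruffling:
                # random contiguous boundary arc
                arc_len = max(1, int(round(pr.rac_arc_fraction * n)))
                start = int(self.rng.integers(0, n))
                mask[(start + np.arange(arc_len)) % n] = True
            else:
                # anterior (lowest-x) boundary arc
                arc_len = max(1, int(round(pr.anterior_arc_fraction * n)))
                order = np.argsort(pos[loop, 0])
                mask[order[:arc_len]] = True
            self._cycle_index[ci] = k
            self._cycle_start[ci] = ref + k * pm.rac_duration
            self._active_entries[sl] = mask
            self._last_rac_onset[loop[mask]] = self._cycle_start[ci]

    # -- integration -------------------------------------------------------

    def compute_forces(self) -> np.ndarray:
        """Total force on every pool vertex at the current time."""
        pm, pr, gt = self.params, self.program, self.genotype
        pos = self.mesh.vertex_pool
        force = np.zeros_like(pos)

        v = pos[self.loop_idx]
        nx = pos[self.nxt_idx]
        pv = pos[self.prv_idx]

        # cortical tension: K_L (s+ + s-); contractility tracks Rho activity
        k_l = pm.line_tension
        if pr.tension_rho_coupling:
            k_l = k_l * self.rho_multiplier(self.t) * gt.rho_mult
        np.add.at(force, self.loop_idx, k_l * ((nx - v) + (pv - v)))

        # area elasticity (gradient discretisation of Eq. area term)
        cross = v[:, 0] * nx[:, 1] - nx[:, 0] * v[:, 1]
        areas = 0.5 * np.bincount(self.cell_of, weights=cross, minlength=self.n_cells)
        a0_eff = self.a0_init * (self.growth_factor if pr.a0_follows_growth else 1.0)
        chord = nx - pv
        r_nor = np.stack([chord[:, 1], -chord[:, 0]], axis=1)
        chord_len = np.hypot(chord[:, 0], chord[:, 1])
        safe = np.where(chord_len > 0, chord_len, 1.0)
        r_nor /= safe[:, None]
        s_grad = 0.5 * chord_len
        d_area = (areas - a0_eff)[self.cell_of]
        np.add.at(
            force,
            self.loop_idx,
            (-pm.area_stiffness * s_grad * d_area)[:, None] * r_nor,
        )

        # Rac protrusion pulses
        tau = self.t - self._cycle_start
        z = (2.0 * tau - pm.rac_duration) / (2.0 * pm.rac_sigma)
        in_pulse = (tau >= 0) & (tau <= pm.rac_duration) & (self._cycle_index >= 0)
        gauss = np.where(
            in_pulse,
            np.exp(-0.5 * z * z) / (pm.rac_sigma * math.sqrt(2 * math.pi)),
            0.0,
        )
        anterior_phase = self.t >= pr.ruffling_end
        pulse_scale = pr.anterior_rac_mult if anterior_phase else 1.0
        mag = (
            pulse_scale * gt.rac_mult * pm.rac_strength
            * gauss[self.cell_of] * self._active_entries
        )
        np.add.at(force, self.loop_idx, mag[:, None] * r_nor)

        # adhesion toward substrate anchors, Hill-gated by Rho activity
        l_eff = pm.rho_level * gt.rho_mult * self.rho_multiplier(self.t)
        hill = hill_factor(l_eff, pm.hill_dissociation, pm.hill_coeff)
        engaged = (self.t - self._last_rac_onset) >= pm.adhesion_delay
        force += (
            pm.cam_strength
            * gt.cam_mult
            * hill
            * engaged[:, None]
            * (self.mesh.anchors - pos)
        )

        # one-sided D-V stress fibers
        if self._fibers_engaged and self.fiber_i.size:
            d = pos[self.fiber_j] - pos[self.fiber_i]
            dist = np.hypot(d[:, 0], d[:, 1])
            ext = np.maximum(dist - self.fiber_l0, 0.0)
            k_eff = pm.fiber_stiffness * gt.fiber_mult * pr.fiber_engaged_mult
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(dist[:, None] > 0, k_eff * (ext / dist)[:, None] * d, 0.0)
            np.add.at(force, self.fiber_i, f)
            np.add.at(force, self.fiber_j, -f)

        # thermal noise
        if pm.noise_strength != 0.0:
            force += pm.noise_strength * self.rng.standard_normal(pos.shape)
        return force

    def _engage_fibers(self) -> None:
        """Freeze D-V spring pairs per cell at the current configuration."""
        pos = self.mesh.vertex_pool
        fi, fj, l0 = [], [], []
        nb = self.program.n_fibers_per_cell
        for ci in range(self.n_cells):
            loop = self.loop_idx[self._cell_slices[ci]]
            xs = pos[loop, 0]
            qs = np.quantile(xs, np.linspace(0, 1, nb + 1))
            for b in range(nb):
                lo, hi = qs[b], qs[b + 1]
                band = loop[(xs >= lo) & (xs <= hi)]
                if band.size < 2:
                    continue
                ys = pos[band, 1]
                i, j = int(band[np.argmin(ys)]), int(band[np.argmax(ys)])
                if i == j:
                    continue
                dist = float(np.hypot(*(pos[j] - pos[i])))
                if dist < 1e-9:
                    continue
                fi.append(i)
                fj.append(j)
                l0.append(dist)
        self.fiber_i = np.asarray(fi, int)
        self.fiber_j = np.asarray(fj, int)
        self.fiber_l0 = np.asarray(l0)
        self._fibers_engaged = True

    def step(self) -> None:
        pm, pr = self.params, self.program
        if not self._fibers_engaged and self.t >= pr.ruffling_end:
            self._engage_fibers()
        self._refresh_rac_targets()
        force = self.compute_forces()
        self.mesh.vertex_pool += (pm.dt / pm.eta_vis) * force
        # substrate advection by oocyte growth (passive-migration pathway)
        if self.t >= self.growth_start and self.g > 0:
            self.mesh.anchors = apply_oocyte_growth(
                self.mesh.anchors, self.g, pm.dt, self.x_posterior
            )
            self.growth_factor *= 1.0 + self.g * pm.dt
        if self.t - self._last_turnover >= pm.anchor_turnover_time:
            self.mesh.anchors = self.mesh.vertex_pool.copy()
            self._last_turnover = self.t
        self.t += pm.dt
        self._steps += 1
        if self._steps % self._nan_guard_every == 0 and not np.all(
            np.isfinite(self.mesh.vertex_pool)
        ):
            raise RuntimeError(
                f"non-finite vertex position at t={self.t:.2f} min "
                f"(genotype {self.genotype.name}, seed {self.seed}); "
                "reduce dt or force magnitudes"
            )

    def run(self, duration: float | None = None, record_every: float = 1.0):
        """Integrate and record frames every ``record_every`` minutes.

        Returns (trajectory, per_frame_table, tissue_table); the trajectory
        is a flat list of BoundaryPolygon records (cell-major per frame).
        """
        from .metrics import circularity, count_ruffle_arcs

        if duration is None:
            duration = self.program.total_duration
        n_steps = int(round(duration / self.params.dt))
        steps_per_frame = max(1, int(round(record_every / self.params.dt)))

        trajectory: list[BoundaryPolygon] = []
        cell_rows, tissue_rows = [], []

        def record() -> None:
            t = round(self.t, 9)
            circs, areas, cxs = [], [], []
            for ci in range(self.n_cells):
                poly = self.mesh.cell_polygon(ci, frame_time=t)
                m = polygon_measures(poly)
                circ = circularity(poly)
                n_ruffles = count_ruffle_arcs(poly)
                trajectory.append(poly)
                cell_rows.append(
                    (
                        poly.cell_id, t, m["area"], m["perimeter"], circ,
                        m["centroid"][0], m["centroid"][1], n_ruffles,
                    )
                )
                circs.append(circ)
                areas.append(m["area"])
                cxs.append(m["centroid"][0])
            recruited = self.onset <= t
            wave_front = (
                float(np.min(np.asarray(cxs)[recruited])) if recruited.any() else np.nan
            )
            tissue_rows.append(
                (
                    t,
                    float(np.mean(circs)),
                    float(np.mean(areas)),
                    float(np.mean(self.centroid_x0 - np.asarray(cxs))),
                    wave_front,
                )
            )

        record()
        for s in range(n_steps):
            self.step()
            if (s + 1) % steps_per_frame == 0:
                record()

        per_frame = pd.DataFrame(
            cell_rows,
            columns=[
                "cell_id", "time_min", "area_um2", "perimeter_um", "circularity",
                "centroid_x", "centroid_y", "ruffle_count",
            ],
        )
        tissue = pd.DataFrame(
            tissue_rows,
            columns=[
                "time_min", "mean_circularity", "mean_area_um2",
                "mean_pa_displacement_um", "wave_front_x_um",
            ],
        )
        return trajectory, per_frame, tissue


def run_protocol(
    genotype: Genotype | str = "WT",
    mode: str = "combined_factor",
    params: ModelParams | None = None,
    program: PhaseProgram | None = None,
    seed: int = 0,
    n_rows: int = 3,
    n_cols: int = 3,
    edge_len: float = 2.0,
    verts_per_edge: int = 4,
    record_every: float = 1.0,
    duration: float | None = None,
):
    """Build a hexagonal patch and run the full phase protocol.

    Returns (trajectory, per_frame_table, tissue_table, simulation).
    """
    params = params or ModelParams()
    program = program or PhaseProgram()
    mesh = hexagonal_tiling(n_rows, n_cols, edge_len, verts_per_edge)
    sim = Simulation(mesh, params, program, genotype, mode=mode, seed=seed)
    trajectory, per_frame, tissue = sim.run(duration, record_every=record_every)
    return trajectory, per_frame, tissue, sim


def params_to_dict(params: ModelParams) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(params)}
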