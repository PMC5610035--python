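"""Vectorized explicit finite-difference integrator for follicle populations.

One engine serves both the single-follicle and the lattice simulations: a
single follicle is a one-site population with zero coupling.  All sites are
advanced together with elementwise numpy operations, so a site's trajectory
is bitwise independent of how many other sites share the arrays; this is what
makes the zero-coupling factorization property hold exactly.

State layout (S sites, N = maximal number of axis nodes):
    L[2, S, N]   free ligand, pathway axis 0 = activator, 1 = inhibitor
    B[2, S, N]   ligand-bound receptor (nonzero only on Region-I nodes)
    m[S]         active node count per site (grid covers [0, length])
    length[S]    current follicle length
    phase[S]     True while in ~anagen
Depth axis: node j sits at x = j*dx, x = 0 at the skin surface, increasing
with depth.  Region I (bulge) is a fixed near-surface interval; Region II
(DP + germ/matrix) is a band of fixed width abutting the moving distal end.
"""

from __future__ import annotations

import dataclasses
import math
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

if TYPE_CHECKING:  # pragma: no cover
    from .hf_core import HFGeometry, PathwayParams, PhaseThresholds

ACT, INH = 0, 1

#: phase codes used throughout (int8 in records)
TELOGEN_CODE, ANAGEN_CODE = 0, 1


class IntegrationError(RuntimeError):
    """Raised when the explicit scheme produced invalid numbers."""


class StabilityError(ValueError):
    """Raised when dt violates the explicit diffusion stability bound."""


def stability_limit(grid_spacing: float, max_diffusion: float) -> float:
    """Maximum admissible dt for the explicit central-difference scheme."""
    if max_diffusion <= 0:
        return math.inf
    return grid_spacing**2 / (2.0 * max_diffusion)


def check_stability(dt: float, grid_spacing: float, max_diffusion: float) -> None:
    limit = stability_limit(grid_spacing, max_diffusion)
    if dt > limit * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt:g} violates the explicit stability bound; "
            f"maximum admissible dt is {limit:g} "
            f"(= grid_spacing^2 / (2 * max diffusion_coeff))"
        )


def trapezoid_mass(field: np.ndarray, m: np.ndarray, dx: float) -> np.ndarray:
    """Trapezoidal integral of per-site fields over their active nodes.

    ``field`` has shape (..., S, N); ``m`` the active node counts (S,).
    """
    S, N = field.shape[-2], field.shape[-1]
    cols = np.arange(N)
    active = cols < m[:, None]
    total = np.where(active, field, 0.0).sum(axis=-1)
    last = np.take_along_axis(field, np.broadcast_to((m - 1)[:, None], field.shape[:-1] + (1,)), axis=-1)[..., 0]
    return dx * (total - 0.5 * (field[..., 0] + last))


def interval_cell_weights(n: int, dx: float, lo: float, hi: float) -> np.ndarray:
    """Fraction of each node's cell [x_j - dx/2, x_j + dx/2] inside [lo, hi]."""
    x = np.arange(n) * dx
    a = np.maximum(x - dx / 2, 0.0)
    b = x + dx / 2
    overlap = np.clip(np.minimum(b, hi) - np.maximum(a, lo), 0.0, None)
    return overlap / dx


def spawn_site_rng(seed: int, site: int) -> np.random.Generator:
    """Counter-based per-site stream: adding sites never perturbs existing ones."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(site,))))


@dataclasses.dataclass
class StepCounters:
    """Bookkeeping for clipped (negative-undershoot) nodes."""

    clip_events: int = 0
    steps: int = 0
    nodes_per_step: int = 0


class SimEngine:
    """Advances S follicles; see module docstring for the state layout."""

    def __init__(
        self,
        geometry: "HFGeometry",
        acts: Sequence["PathwayParams"],
        inhs: Sequence["PathwayParams"],
        thresholds: Sequence["PhaseThresholds"],
        growth_laws: Sequence[Callable[[np.ndarray, np.ndarray], np.ndarray]],
        dt: float,
        adjacency: sparse.spmatrix | None = None,
        coupling_strength: float = 0.0,
        seed: int | None = None,
        clip_abort_fraction: float = 0.01,
        exchange_band: np.ndarray | None = None,
    ):
        S = len(acts)
        if not (len(inhs) == len(thresholds) == len(growth_laws) == S):
            raise ValueError("per-site parameter sequences must have equal length")
        self.geometry = geometry
        self.dx = geometry.grid_spacing
        self.dt = float(dt)
        self.S = S
        self.N = geometry.max_nodes
        max_D = max(max(a.diffusion_coeff, i.diffusion_coeff) for a, i in zip(acts, inhs))
        check_stability(self.dt, self.dx, max_D)

        def stack(attr):
            return np.array(
                [[getattr(p, attr) for p in acts], [getattr(p, attr) for p in inhs]],
                dtype=float,
            )[:, :, None]  # (2, S, 1) for broadcasting over nodes

        self.D = stack("diffusion_coeff")
        self.s1 = stack("production_region1")
        self.k_on = stack("bind_on")
        self.k_off = stack("bind_off")
        self.k_deg = stack("degradation")
        self.R_tot = stack("receptor_total")
        self.sigma = stack("noise_amplitude")
        self.e1 = stack("extra_source_region1")
        self.s2 = {
            code: np.array(
                [[p.production_region2[code] for p in acts],
                 [p.production_region2[code] for p in inhs]],
                dtype=float,
            )[:, :, None]
            for code in (TELOGEN_CODE, ANAGEN_CODE)
        }

        self.theta_act = np.array([t.activation_threshold for t in thresholds])
        self.theta_term = np.array([t.termination_threshold for t in thresholds])
        self.refractory = np.array([t.refractory_min_duration for t in thresholds])
        self.growth_laws = list(growth_laws)

        # Region I weights are static (interval fixed, inside the minimal length)
        self.w1 = interval_cell_weights(self.N, self.dx, *geometry.region1_interval)
        if not np.any(self.w1 > 0):
            raise ValueError("Region I interval contains no grid node")
        self.idx1 = np.where(self.w1 > 0)[0]
        self._w1_norm = self.w1[self.idx1] / self.w1[self.idx1].sum()

        # state
        self.L = np.zeros((2, S, self.N))
        self.B = np.zeros((2, S, self.N))
        self.length = np.full(S, geometry.length_min, dtype=float)
        self.m = self._nodes_for(self.length)
        self.phase = np.zeros(S, dtype=bool)  # False = ~telogen
        self.phase_elapsed = np.full(S, np.inf)  # dwell guard satisfied at start
        self.t = 0.0
        self.prev_C = self.signal()
        self.anagen_count = np.zeros(S, dtype=int)
        self.transitions: list[tuple[float, int, int, int, int]] = []
        self.counters = StepCounters(nodes_per_step=2 * 2 * S * self.N)

        # coupling: exchange applies on a fixed near-surface band common to
        # all follicles; default = every node within the resting length
        if exchange_band is None:
            n_rest = int(math.floor(geometry.length_min / self.dx + 1e-9)) + 1
            exchange_band = np.arange(n_rest)
        self.band_idx = np.asarray(exchange_band, dtype=int)
        self.kappa = float(coupling_strength)
        if adjacency is not None:
            self.adjacency = sparse.csr_matrix(adjacency)
            self.degree = np.asarray(self.adjacency.sum(axis=1)).ravel()
        else:
            self.adjacency = None
            self.degree = None

        noise_on = bool(np.any(self.sigma > 0))
        self.rngs: list[np.random.Generator] | None = None
        if noise_on:
            if seed is None:
                raise ValueError("noise_amplitude > 0 requires a seed")
            self.rngs = [spawn_site_rng(seed, i) for i in range(S)]
        self.clip_abort_fraction = clip_abort_fraction
        self._cols = np.arange(self.N)

    # ------------------------------------------------------------------ state

    def _nodes_for(self, length: np.ndarray) -> np.ndarray:
        return (np.floor(length / self.dx + 1e-9)).astype(int) + 1

    def active_mask(self) -> np.ndarray:
        return self._cols[None, :] < self.m[:, None]

    def region2_weights(self) -> np.ndarray:
        """Per-site cell weights of the moving Region II band (S, N)."""
        lo = (self.length - self.geometry.region2_width)[:, None]
        hi = self.length[:, None]
        x = self._cols * self.dx
        a = np.maximum(x - self.dx / 2, 0.0)[None, :]
        b = np.broadcast_to(x + self.dx / 2, (self.S, self.N)).copy()
        # the distal active cell extends to the true length so no source mass
        # falls beyond the grid (total Region-II production is exact in length)
        b[np.arange(self.S), self.m - 1] = np.maximum(
            b[np.arange(self.S), self.m - 1], self.length
        )
        w = np.clip(np.minimum(b, hi) - np.maximum(a, lo), 0.0, None) / self.dx
        return np.where(self.active_mask(), w, 0.0)

    def signal(self) -> np.ndarray:
        """Growth signal C: Region-I weighted mean of bound_act - bound_inh.

        Summation runs along the node axis so the result is bitwise
        independent of how many sites share the state arrays.
        """
        diff = self.B[ACT][:, self.idx1] - self.B[INH][:, self.idx1]
        return (diff * self._w1_norm).sum(axis=-1)

    # ------------------------------------------------------------- substeps

    def laplacian(self, F: np.ndarray) -> np.ndarray:
        """Central-difference Laplacian with reflecting (no-flux) ends.

        Ghost nodes mirror the first interior node (L[-1] := L[1],
        L[m] := L[m-2]), which conserves the trapezoidal mass exactly.
        """
        S, N = self.S, self.N
        j = self._cols
        left = np.maximum(j - 1, 0)
        left = np.where(j == 0, 1, left)
        right = np.broadcast_to(j + 1, (S, N)).copy()
        last = self.m - 1
        right[np.arange(S), last] = np.maximum(last - 1, 0)
        right = np.minimum(right, N - 1)
        lap = F[..., left] - 2.0 * F + np.take_along_axis(
            F, np.broadcast_to(right, F.shape[:-2] + (S, N)), axis=-1
        )
        return np.where(self.active_mask(), lap, 0.0)

    def reaction_diffusion_substep(self) -> None:
        dt, dx = self.dt, self.dx
        active = self.active_mask()
        w2 = self.region2_weights()
        sched = np.where(self.phase[None, :, None], self.s2[ANAGEN_CODE], self.s2[TELOGEN_CODE])
        prod = self.s1 * self.w1[None, None, :] + sched * w2[None, :, :]

        # receptor density follows the Region-I indicator with partial-cell
        # weights so the discretization converges under grid refinement
        Rprof = self.R_tot * self.w1[None, None, :]
        free = Rprof - self.B
        bind = self.k_on * self.L * free

        lap = self.laplacian(self.L)
        dL = self.D * lap / dx**2 + prod - bind + self.k_off * self.B
        dB = bind - (self.k_off + self.k_deg) * self.B + self.e1 * self.w1[None, None, :]
        self.L += dt * np.where(active[None], dL, 0.0)
        self.B += dt * np.where(active[None], dB, 0.0)

        if self.rngs is not None:
            amp = self.sigma[:, :, 0] * math.sqrt(dt)  # (2, S)
            wn = self.w1[self.idx1]
            for i in range(self.S):
                if amp[0, i] > 0 or amp[1, i] > 0:
                    xi = self.rngs[i].standard_normal((2, self.idx1.size))
                    self.B[:, i, self.idx1] += amp[:, i, None] * wn[None, :] * xi

        self._clip_fields()
        if not (np.isfinite(self.L).all() and np.isfinite(self.B).all()):
            bad = "ligand" if not np.isfinite(self.L).all() else "bound-receptor"
            raise IntegrationError(f"non-finite values in {bad} field at t={self.t:g}")

    def _clip_fields(self) -> None:
        Rprof = self.R_tot * self.w1[None, None, :]
        neg = int((self.L < 0).sum() + (self.B < 0).sum())
        over = int((self.B > Rprof).sum())
        clipped = neg + over
        self.counters.clip_events += clipped
        # Zero-floor undershoots from the noise term are tiny and benign;
        # a genuine explicit-scheme blow-up clips many nodes by a large
        # margin, so abort only when both signatures are present.
        if clipped > max(self.clip_abort_fraction * self.counters.nodes_per_step, 1):
            worst = max(-float(self.L.min()), -float(self.B.min()),
                        float((self.B - Rprof).max()))
            if worst > 1e-3 * float(self.R_tot.max()):
                raise IntegrationError(
                    f"{clipped} nodes clipped by up to {worst:g} in one step "
                    f"at t={self.t:g} (> {self.clip_abort_fraction:.0%} of "
                    "nodes); reduce dt or noise_amplitude"
                )
        np.clip(self.L, 0.0, None, out=self.L)
        np.clip(self.B, 0.0, Rprof, out=self.B)

    def coupling_substep(self) -> None:
        """Inter-follicular ligand exchange over the shared depth band."""
        if self.adjacency is None or self.kappa == 0.0:
            return
        band = self.band_idx
        for p in (ACT, INH):
            X = self.L[p][:, band]
            self.L[p][:, band] = X + self.kappa * self.dt * (
                self.adjacency @ X - self.degree[:, None] * X
            )

    def growth_substep(self, C: np.ndarray) -> None:
        v = np.empty(self.S)
        for i, law in enumerate(self.growth_laws):
            v[i] = law(C[i], bool(self.phase[i]))
        new_len = np.clip(
            self.length + v * self.dt, self.geometry.length_min, self.geometry.length_max
        )
        new_m = self._nodes_for(new_len)
        changed = np.where(new_m != self.m)[0]
        for i in changed:
            self._regrid_site(i, int(self.m[i]), int(new_m[i]))
        self.length = new_len
        self.m = new_m

    def _regrid_site(self, i: int, old_m: int, new_m: int) -> None:
        """Node insertion/removal at the distal end.

        The interpolation never redistributes mass over the surviving
        domain.  Elongation appends nodes carrying the extrapolated distal
        boundary value: the freshly built matrix tissue derives from the
        producing compartment and brings its local ligand concentration
        with it.  Retraction is apoptotic involution: the removed distal
        tissue takes its ligand with it.
        """
        for p in (ACT, INH):
            f = self.L[p, i]
            if new_m > old_m:
                f[old_m:new_m] = f[old_m - 1]  # constant extrapolation
            else:
                f[new_m:old_m] = 0.0
                self.B[p, i, new_m:old_m] = 0.0

    def checkpoint_substep(self, C: np.ndarray) -> None:
        up = (
            (~self.phase)
            & (self.phase_elapsed >= self.refractory)
            & (self.prev_C < self.theta_act)
            & (C >= self.theta_act)
        )
        down = (
            self.phase
            & (self.phase_elapsed >= self.refractory)
            & (self.prev_C >= self.theta_term)
            & (C < self.theta_term)
        )
        t_event = self.t + self.dt
        for i in np.where(up)[0]:
            self.anagen_count[i] += 1
            self.transitions.append(
                (t_event, int(i), TELOGEN_CODE, ANAGEN_CODE, int(self.anagen_count[i]))
            )
        for i in np.where(down)[0]:
            self.transitions.append(
                (t_event, int(i), ANAGEN_CODE, TELOGEN_CODE, int(self.anagen_count[i]))
            )
        flip = up | down
        self.phase = np.where(flip, ~self.phase, self.phase)
        self.phase_elapsed = np.where(flip, 0.0, self.phase_elapsed + self.dt)

    # ----------------------------------------------------------------- step

    def step(self) -> None:
        self.reaction_diffusion_substep()
        self.coupling_substep()
        C = self.signal()
        self.growth_substep(C)
        self.checkpoint_substep(C)
        self.prev_C = C
        self.t += self.dt
        self.counters.steps += 1

    def run(self, horizon: float, output_stride: float | None = None) -> "RawRecord":
        n_steps = int(round(horizon / self.dt))
        stride = max(1, int(round((output_stride or self.dt) / self.dt)))
        rec = RawRecord.allocate(self, n_steps // stride + 1)
        rec.capture(self, 0)
        k = 0
        for step in range(1, n_steps + 1):
            self.step()
            if step % stride == 0:
                k += 1
                rec.capture(self, k)
        rec.trim(k + 1)
        rec.transitions = self.transitions_frame()
        return rec

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.transitions,
            columns=["time", "site", "from_phase", "to_phase", "cycle_index"],
        )

    # ------------------------------------------------------------ snapshots

    def snapshot(self) -> dict:
        return {
            "L": self.L.copy(),
            "B": self.B.copy(),
            "length": self.length.copy(),
            "m": self.m.copy(),
            "phase": self.phase.copy(),
            "phase_elapsed": self.phase_elapsed.copy(),
            "prev_C": self.prev_C.copy(),
        }

    def restore_site(self, i: int, snap: dict, j: int = 0) -> None:
        """Load site ``j`` of a snapshot into site ``i`` of this engine."""
        self.L[:, i] = snap["L"][:, j]
        self.B[:, i] = snap["B"][:, j]
        self.length[i] = snap["length"][j]
        self.m[i] = snap["m"][j]
        self.phase[i] = snap["phase"][j]
        self.phase_elapsed[i] = snap["phase_elapsed"][j]
        self.prev_C = self.signal()


@dataclasses.dataclass
class RawRecord:
    """Strided engine output: arrays of shape (T,) or (T, S)."""

    times: np.ndarray
    phase: np.ndarray
    length: np.ndarray
    signal: np.ndarray
    mean_bound_act: np.ndarray
    mean_bound_inh: np.ndarray
    transitions: pd.DataFrame | None = None

    @classmethod
    def allocate(cls, eng: SimEngine, n: int) -> "RawRecord":
        S = eng.S
        return cls(
            times=np.zeros(n),
            phase=np.zeros((n, S), dtype=np.int8),
            length=np.zeros((n, S)),
            signal=np.zeros((n, S)),
            mean_bound_act=np.zeros((n, S)),
            mean_bound_inh=np.zeros((n, S)),
        )

    def capture(self, eng: SimEngine, k: int) -> None:
        self.times[k] = eng.t
        self.phase[k] = eng.phase.astype(np.int8)
        self.length[k] = eng.length
        self.signal[k] = eng.signal()
        self.mean_bound_act[k] = (eng.B[ACT][:, eng.idx1] * eng._w1_norm).sum(axis=-1)
        self.mean_bound_inh[k] = (eng.B[INH][:, eng.idx1] * eng._w1_norm).sum(axis=-1)

    def trim(self, n: int) -> None:
        for name in ("times", "phase", "length", "signal", "mean_bound_act", "mean_bound_inh"):
            setattr(self, name, getattr(self, name)[:n])
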