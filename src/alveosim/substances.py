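"""Extracellular substance fields: explicit diffusion with decay and binding.

Each substance lives on a coarse voxel grid (default 4x4x4 voxels of side
500 um) as a concentration in g/cm^3.  Fields advance by the explicit
forward-time centred-space (FTCS) scheme with zero-flux ("closed")
boundaries, first-order decay, pairwise mass-action binding losses
(e.g. MMP degrading ECM, TIMP neutralising MMP) and first-order conversion
(latent TGF-beta activating).  The explicit scheme is stable when
``dt <= dx^2 / (6 D)`` for every substance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryConfig, UM_PER_CM

__all__ = [
    "SUBSTANCE_NAMES",
    "BindingTerm",
    "SubstanceSpec",
    "FieldSet",
    "cfl_max_dt",
]

SUBSTANCE_NAMES = (
    "MCP1",
    "TNFa",
    "FGF2",
    "TGFb_active",
    "TGFb_inactive",
    "PDGF",
    "IL13",
    "MMP",
    "TIMP",
    "ECM",
)


@dataclass(frozen=True)
class BindingTerm:
    """Mass-action interaction seen from one substance.

    ``role`` is ``"consumed"`` (this substance loses coeff*C*C_partner),
    ``"consuming"`` (the partner loses; this substance is unchanged) or
    ``"converted_to:<name>"`` (first-order conversion at rate ``coeff`` per
    second; ``partner`` is ignored).
    """

    partner: str | None
    coeff: float  # (g/cm^3)^-1 s^-1 for pair terms, s^-1 for conversions
    role: str = "consumed"


@dataclass(frozen=True)
class SubstanceSpec:
    name: str
    diff_coeff_um2_s: float = 0.0
    decay_per_s: float = 0.0
    init_conc: float = 0.0
    bindings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.diff_coeff_um2_s < 0 or self.decay_per_s < 0:
            raise ValueError(f"{self.name}: negative diffusion or decay rate")
        for b in self.bindings:
            if b.coeff < 0:
                raise ValueError(f"{self.name}: negative binding coefficient")
        if self.name == "ECM" and self.diff_coeff_um2_s != 0.0:
            raise ValueError("ECM must not diffuse")


def cfl_max_dt(spec: SubstanceSpec, voxel_side_um: float) -> float:
    """Largest stable explicit time step for one substance (seconds)."""
    if spec.diff_coeff_um2_s == 0.0:
        return np.inf
    return voxel_side_um**2 / (6.0 * spec.diff_coeff_um2_s)


def _laplacian_closed(c: np.ndarray) -> np.ndarray:
    """7-point stencil Laplacian (unscaled) with mirrored boundary values.

    Mirroring the edge value gives a zero normal gradient, i.e. an insulated
    box: no mass crosses the faces.
    """
    p = np.pad(c, 1, mode="edge")
    return (
        p[2:, 1:-1, 1:-1]
        + p[:-2, 1:-1, 1:-1]
        + p[1:-1, 2:, 1:-1]
        + p[1:-1, :-2, 1:-1]
        + p[1:-1, 1:-1, 2:]
        + p[1:-1, 1:-1, :-2]
        - 6.0 * c
    )


class FieldSet:
    """All substance fields on one grid plus their kinetic parameters.

    Concentrations are stored as one stacked (n_substances, n, n, n) array;
    ``fields[name]`` exposes a writable view of one substance's grid.
    """

    def __init__(self, specs: dict, geometry: GeometryConfig | None = None):
        self.geometry = geometry or GeometryConfig()
        n = self.geometry.n_voxels_per_side
        self.specs = dict(specs)
        self._names = list(self.specs)
        self._index = {name: i for i, name in enumerate(self._names)}
        self.data = np.empty((len(self._names), n, n, n), dtype=float)
        for i, name in enumerate(self._names):
            self.data[i] = self.specs[name].init_conc
        self.fields: dict = {name: self.data[i] for i, name in enumerate(self._names)}
        self._diff = np.array(
            [self.specs[m].diff_coeff_um2_s for m in self._names]
        )[:, None, None, None]
        self._decay = np.array(
            [self.specs[m].decay_per_s for m in self._names]
        )[:, None, None, None]
        self.clamp_events = 0
        # compiled reaction terms: (victim, a, b, coeff) and (src, dst, rate)
        self._pair_terms: list = []
        self._conversions: list = []
        for name, spec in self.specs.items():
            for b in spec.bindings:
                if b.role == "consumed":
                    self._pair_terms.append((name, name, b.partner, b.coeff))
                elif b.role == "consuming":
                    self._pair_terms.append((b.partner, name, b.partner, b.coeff))
                elif b.role.startswith("converted_to:"):
                    self._conversions.append((name, b.role.split(":", 1)[1], b.coeff))
                else:
                    raise ValueError(f"unknown binding role {b.role!r}")
        self._pair_idx = [
            (self._index[v], self._index[a], self._index[b], k)
            for v, a, b, k in self._pair_terms
        ]
        self._conv_idx = [
            (self._index[s], self._index[d], r) for s, d, r in self._conversions
        ]

    # -- geometry helpers -----------------------------------------------
    @property
    def voxel_side_cm(self) -> float:
        return self.geometry.voxel_side_um / UM_PER_CM

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_side_cm**3

    def _voxel(self, position) -> tuple:
        from .geometry import voxel_of

        return voxel_of(np.asarray(position, dtype=float), self.geometry)

    # -- point operations ----------------------------------------------
    def deposit(self, name: str, position, amount_g: float) -> None:
        """Add ``amount_g`` grams of substance into the containing voxel."""
        if not np.isfinite(amount_g):
            raise ValueError("deposit amount must be finite")
        self.fields[name][self._voxel(position)] += amount_g / self.voxel_volume_cm3

    def deposit_rows(self, name: str, idx: np.ndarray, amounts_g: np.ndarray) -> None:
        """Vectorised deposit: ``idx`` is (k, 3) voxel indices."""
        if idx.size == 0:
            return
        np.add.at(
            self.fields[name],
            (idx[:, 0], idx[:, 1], idx[:, 2]),
            np.asarray(amounts_g, dtype=float) / self.voxel_volume_cm3,
        )

    def sample(self, name: str, position) -> float:
        """Concentration at the voxel containing ``position`` (no interpolation)."""
        return float(self.fields[name][self._voxel(position)])

    def sample_rows(self, name: str, idx: np.ndarray) -> np.ndarray:
        return self.fields[name][idx[:, 0], idx[:, 1], idx[:, 2]]

    def mean_concentration(self, name: str) -> float:
        """Unweighted mean over all voxels (the whole-space average)."""
        return float(self.fields[name].mean())

    def total_mass(self, name: str) -> float:
        return float(self.fields[name].sum() * self.voxel_volume_cm3)

    # -- time stepping ---------------------------------------------------
    def _padded_buffer(self, c: np.ndarray) -> np.ndarray:
        """Edge-replicated copy of the stack (zero-flux ghost cells), reused."""
        buf = getattr(self, "_pad_buf", None)
        if buf is None or buf.shape[1:] != tuple(s + 2 for s in c.shape[1:]):
            buf = np.empty((c.shape[0],) + tuple(s + 2 for s in c.shape[1:]))
            self._pad_buf = buf
        buf[:, 1:-1, 1:-1, 1:-1] = c
        buf[:, 0] = buf[:, 1]
        buf[:, -1] = buf[:, -2]
        buf[:, :, 0] = buf[:, :, 1]
        buf[:, :, -1] = buf[:, :, -2]
        buf[:, :, :, 0] = buf[:, :, :, 1]
        buf[:, :, :, -1] = buf[:, :, :, -2]
        return buf

    def max_stable_dt(self) -> float:
        return min(cfl_max_dt(s, self.geometry.voxel_side_um) for s in self.specs.values())

    def step_diffusion(self, dt: float) -> None:
        """One FTCS step of length ``dt`` seconds for every substance.

        Reaction terms (decay, pair binding, conversion) are evaluated on the
        pre-step concentrations so paired losses are symmetric.  Negative
        results are clamped to zero and counted in ``clamp_events``.
        """
        h = self.geometry.voxel_side_um
        for name, spec in self.specs.items():
            limit = cfl_max_dt(spec, h)
            if dt > limit * (1.0 + 1e-12):
                raise ValueError(
                    f"FTCS unstable for {name}: dt={dt:g}s exceeds max {limit:g}s"
                )
        c = self.data
        p = self._padded_buffer(c)
        lap = (
            p[:, 2:, 1:-1, 1:-1]
            + p[:, :-2, 1:-1, 1:-1]
            + p[:, 1:-1, 2:, 1:-1]
            + p[:, 1:-1, :-2, 1:-1]
            + p[:, 1:-1, 1:-1, 2:]
            + p[:, 1:-1, 1:-1, :-2]
            - 6.0 * c
        )
        delta = (self._diff / h**2) * lap - self._decay * c
        for v, a, b, k in self._pair_idx:
            delta[v] -= k * c[a] * c[b]
        for s, d, r in self._conv_idx:
            flux = r * c[s]
            delta[s] -= flux
            delta[d] += flux
        c += dt * delta
        neg = c < 0.0
        if neg.any():
            self.clamp_events += int(neg.sum())
            c[neg] = 0.0

    def advance(self, seconds: float, max_substep: float | None = None) -> None:
        """Advance all fields by ``seconds``, sub-stepping at a stable dt."""
        if seconds <= 0:
            return
        limit = self.max_stable_dt()
        if max_substep is not None:
            limit = min(limit, max_substep)
        n = max(1, int(np.ceil(seconds / limit)))
        dt = seconds / n
        for _ in range(n):
            self.step_diffusion(dt)

    def copy(self) -> "FieldSet":
        new = FieldSet(self.specs, self.geometry)
        new.data[...] = self.data
        new.clamp_events = self.clamp_events
        return new
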