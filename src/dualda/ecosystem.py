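"""An 11-variable NEMURO-type plankton ecosystem model on a vertical column.

State variables per grid cell (nitrogen pools in mmol N m^-3, silicon pools
in mmol Si m^-3):

======  =====================================================
PS      small phytoplankton (e.g. flagellates)
PL      large phytoplankton (diatoms; silicified)
ZS      small zooplankton
ZL      large zooplankton
ZP      predatory zooplankton
NO3     nitrate
NH4     ammonium
DON     dissolved organic nitrogen
PON     particulate organic nitrogen (detritus)
SiOH4   silicic acid
Opal    biogenic silica (diatom shells, detrital)
======  =====================================================

Process set: nutrient- and light-limited photosynthesis (Michaelis-Menten in
NO3, NH4 and - for PL - silicic acid, with ammonium inhibition of nitrate
uptake and Steele light limitation), Ivlev grazing (ZS on PS; ZL on PS, PL,
ZS; ZP on ZL), linear + quadratic mortality to detritus, decomposition
PON -> DON -> NH4, nitrification NH4 -> NO3, opal dissolution, sinking of
PON and Opal (first-order upwind), explicit vertical diffusion, and light
attenuation by water plus phytoplankton self-shading.  Diatom shell silicon
is carried implicitly as ``r_si_n * PL``; every tendency is an explicit
transfer between compartments, so total nitrogen (and silicon within the Si
sub-cycle) is conserved by construction.

Every arithmetic operation goes through overloaded scalars, so the exact
same code yields the nonlinear solution (floats), the tangent linear model
(dual scalars) and the column-by-column adjoint (multi-dual scalars).  The
step is decomposed into declared segments - transport, light, pointwise
biology, sinking - so the reduced-cost segmented adjoint applies; transport,
sinking and light carry hand-coded linear/analytic adjoints as well,
mirroring systems where physics adjoints pre-exist.

No positivity clipping occurs inside differentiated code: clipping would
destroy TLM/adjoint consistency.  Stability is handled by time-step limits,
and non-negativity of trajectories is checked where the contract demands
it, never enforced silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, Optional, Tuple

import numpy as np

from . import dual as dm
from .dual import DualScalar, MultiDualScalar
from .engine import ModelFunction
from .segments import (
    ColumnFunctionSegment,
    EulerProcessSegment,
    Process,
    SegmentedModel,
    TridiagonalSegment,
)
from .state import Layout, StateVector, as_values

__all__ = [
    "VARIABLES",
    "IRRADIANCE",
    "BgcParams",
    "ColumnGrid",
    "ColumnModel",
    "StabilityError",
    "NegativeStateError",
    "bgc_source_step",
    "light_attenuation",
    "sinking_step",
    "transport_step",
    "model_step",
    "chlorophyll_diagnostic",
    "default_initial_state",
]

DAY = 86400.0  # seconds

VARIABLES: Tuple[str, ...] = (
    "PS", "PL", "ZS", "ZL", "ZP",
    "NO3", "NH4", "DON", "PON", "SiOH4", "Opal",
)
#: nitrogen-currency pools (everything except the silicon pools)
NITROGEN_POOLS = ("PS", "PL", "ZS", "ZL", "ZP", "NO3", "NH4", "DON", "PON")
IRRADIANCE = "IRR"  # diagnostic variable on the augmented layout


class StabilityError(ValueError):
    """Explicit time step violates a diffusion or advection stability limit."""


class NegativeStateError(ValueError):
    """A biogeochemical source step received a negative concentration."""


@dataclass(frozen=True)
class BgcParams:
    """Biogeochemical rate parameters; SI-consistent units (per second, m, mmol).

    Defaults are a plausible NEMURO-style mid-latitude configuration; they
    parameterize the process set, not any particular published site.
    """

    # photosynthesis
    vmax_ps: float = 0.4 / DAY        # 1/s, max growth small phytoplankton
    vmax_pl: float = 0.8 / DAY        # 1/s, max growth large phytoplankton
    k_no3_ps: float = 1.0             # mmol N/m3 half-saturation
    k_nh4_ps: float = 0.1
    k_no3_pl: float = 3.0
    k_nh4_pl: float = 0.3
    k_si_pl: float = 6.0              # mmol Si/m3
    psi_nh4: float = 1.5              # m3/mmol, ammonium inhibition of NO3 uptake
    i_opt: float = 100.0              # W/m2, Steele optimal irradiance
    gamma_exud: float = 0.135         # fraction of uptake exuded as DON
    # Ivlev grazing
    gmax_zs_ps: float = 0.4 / DAY     # 1/s
    gmax_zl_ps: float = 0.1 / DAY
    gmax_zl_pl: float = 0.4 / DAY
    gmax_zl_zs: float = 0.4 / DAY
    gmax_zp_zl: float = 0.4 / DAY
    ivlev: float = 1.4                # m3/mmol
    graz_threshold: float = 0.0       # mmol/m3 feeding threshold (0 = smooth)
    alpha_assim: float = 0.7          # assimilated fraction of grazed N
    beta_growth: float = 0.3          # grazer growth fraction of grazed N
    # mortality
    m0_phyto: float = 0.02 / DAY      # 1/s linear
    m2_phyto: float = 0.025 / DAY     # m3/(mmol s) quadratic
    m0_zoo: float = 0.02 / DAY
    m2_zoo: float = 0.06 / DAY
    # remineralization
    r_pon_don: float = 0.10 / DAY     # 1/s decomposition PON -> DON
    r_pon_nh4: float = 0.05 / DAY     # 1/s decomposition PON -> NH4
    r_don_nh4: float = 0.02 / DAY     # 1/s remineralization DON -> NH4
    r_nitrif: float = 0.03 / DAY      # 1/s nitrification NH4 -> NO3
    r_opal_diss: float = 0.01 / DAY   # 1/s opal dissolution
    # sinking
    w_pon: float = 40.0 / DAY         # m/s
    w_opal: float = 40.0 / DAY
    # light
    k_water: float = 0.04             # 1/m attenuation by sea water
    k_shade: float = 0.03             # m2/mmol N self-shading by PS+PL
    # stoichiometry and diagnostics
    r_si_n: float = 2.0               # mol Si per mol N in diatoms
    chl_ratio: float = 1.59           # mg chl a per mmol N (fixed ratio)
    # optional Q10 temperature dependence (off by default)
    q10: float = 2.0
    temperature: Optional[float] = None  # deg C; None disables the factor

    def __post_init__(self):
        for f in fields(self):
            if f.name in ("graz_threshold", "temperature"):
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"BgcParams.{f.name} must be > 0, got {v}")

    @property
    def temp_factor(self) -> float:
        if self.temperature is None:
            return 1.0
        return self.q10 ** ((self.temperature - 10.0) / 10.0)

    def replace(self, **kw) -> "BgcParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ColumnGrid:
    """Vertical column: surface at index 0, depth increasing downward."""

    dz: np.ndarray                     # layer thicknesses, m
    kappa: np.ndarray = None           # interface diffusivities, m2/s (K-1)
    dt: float = 3600.0                 # s

    def __post_init__(self):
        object.__setattr__(self, "dz", np.atleast_1d(np.asarray(self.dz, float)))
        if np.any(self.dz <= 0):
            raise ValueError("layer thicknesses must be > 0")
        K = self.dz.size
        kappa = self.kappa
        if kappa is None:
            kappa = np.full(max(K - 1, 0), 1e-4)
        kappa = np.atleast_1d(np.asarray(kappa, float))
        if kappa.size == 1 and K > 2:
            kappa = np.full(K - 1, float(kappa[0]))
        if kappa.size != max(K - 1, 0):
            raise ValueError(f"need {K - 1} interface diffusivities, got {kappa.size}")
        object.__setattr__(self, "kappa", kappa)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if K > 1:
            s = self.stability_number
            if s > 0.5:
                raise StabilityError(
                    f"explicit-diffusion stability number {s:.3f} > 0.5; "
                    "reduce dt or kappa, or thicken layers"
                )

    @property
    def n_layers(self) -> int:
        return self.dz.size

    @property
    def stability_number(self) -> float:
        if self.n_layers < 2:
            return 0.0
        dzh = 0.5 * (self.dz[:-1] + self.dz[1:])
        s_up = self.kappa * self.dt / (self.dz[:-1] * dzh)
        s_dn = self.kappa * self.dt / (self.dz[1:] * dzh)
        return float(max(s_up.max(), s_dn.max()))

    @classmethod
    def uniform(cls, n_layers: int = 5, dz: float = 5.0,
                kappa: float = 1e-4, dt: float = 3600.0) -> "ColumnGrid":
        return cls(np.full(n_layers, dz), np.full(max(n_layers - 1, 0), kappa), dt)


def make_layout(n_layers: int) -> Layout:
    return Layout(VARIABLES, n_layers)


def make_layout_aug(n_layers: int) -> Layout:
    return Layout(VARIABLES + (IRRADIANCE,), n_layers)


# ---------------------------------------------------------------------------
# pointwise biological processes
# ---------------------------------------------------------------------------


def _steele(irr, i_opt: float):
    """Steele light limitation (I/I_opt)*exp(1 - I/I_opt); smooth, peak 1."""
    r = irr / i_opt
    return r * dm.exp(1.0 - r)


def _growth_tendency(local, p: BgcParams, small: bool):
    """Photosynthesis with exudation; returns the transfer dict."""
    if small:
        P, kno3, knh4, vmax = local["PS"], p.k_no3_ps, p.k_nh4_ps, p.vmax_ps
    else:
        P, kno3, knh4, vmax = local["PL"], p.k_no3_pl, p.k_nh4_pl, p.vmax_pl
    no3, nh4 = local["NO3"], local["NH4"]
    light = _steele(local[IRRADIANCE], p.i_opt)
    rate = vmax * p.temp_factor * light * P
    u_no3 = rate * (no3 / (no3 + kno3)) * dm.exp(-p.psi_nh4 * nh4)
    u_nh4 = rate * (nh4 / (nh4 + knh4))
    if not small:
        si_lim = local["SiOH4"] / (local["SiOH4"] + p.k_si_pl)
        u_no3 = u_no3 * si_lim
        u_nh4 = u_nh4 * si_lim
    uptake = u_no3 + u_nh4
    growth = (1.0 - p.gamma_exud) * uptake
    out = {
        "NO3": -u_no3,
        "NH4": -u_nh4,
        "DON": p.gamma_exud * uptake,
    }
    if small:
        out["PS"] = growth
    else:
        out["PL"] = growth
        out["SiOH4"] = -p.r_si_n * growth  # silicon built into diatom shells
    return out


def _ps_growth(local, p: BgcParams, ctx):
    return _growth_tendency(local, p, small=True)


def _pl_growth(local, p: BgcParams, ctx):
    return _growth_tendency(local, p, small=False)


def _ivlev(prey, p: BgcParams):
    g = 1.0 - dm.exp(p.ivlev * (p.graz_threshold - prey))
    # threshold form: no feeding below the threshold concentration
    return dm.maximum(0.0, g)


def _grazing(local, p: BgcParams, ctx):
    tf = p.temp_factor
    flows = [  # (prey, grazer, rate)
        ("PS", "ZS", p.gmax_zs_ps * tf * _ivlev(local["PS"], p) * local["ZS"]),
        ("PS", "ZL", p.gmax_zl_ps * tf * _ivlev(local["PS"], p) * local["ZL"]),
        ("PL", "ZL", p.gmax_zl_pl * tf * _ivlev(local["PL"], p) * local["ZL"]),
        ("ZS", "ZL", p.gmax_zl_zs * tf * _ivlev(local["ZS"], p) * local["ZL"]),
        ("ZL", "ZP", p.gmax_zp_zl * tf * _ivlev(local["ZL"], p) * local["ZP"]),
    ]
    out: dict = {v: 0.0 for v in ("PS", "PL", "ZS", "ZL", "ZP", "NH4", "PON", "Opal")}
    a, b = p.alpha_assim, p.beta_growth
    for prey, grazer, g in flows:
        out[prey] = out[prey] - g
        out[grazer] = out[grazer] + b * g
        out["NH4"] = out["NH4"] + (a - b) * g        # excretion
        out["PON"] = out["PON"] + (1.0 - a) * g      # egestion
        if prey == "PL":  # diatom shells are egested, not assimilated
            out["Opal"] = out["Opal"] + p.r_si_n * g
    return out


def _mortality(local, p: BgcParams, ctx):
    out: dict = {}
    pon = 0.0
    for v, m0, m2 in (
        ("PS", p.m0_phyto, p.m2_phyto),
        ("PL", p.m0_phyto, p.m2_phyto),
        ("ZS", p.m0_zoo, p.m2_zoo),
        ("ZL", p.m0_zoo, p.m2_zoo),
        ("ZP", p.m0_zoo, p.m2_zoo),
    ):
        c = local[v]
        m = (m0 + m2 * c) * c
        out[v] = -m
        pon = pon + m
        if v == "PL":
            out["Opal"] = p.r_si_n * m
    out["PON"] = pon
    return out


def _remineralization(local, p: BgcParams, ctx):
    pon, don, nh4, opal = local["PON"], local["DON"], local["NH4"], local["Opal"]
    to_don = p.r_pon_don * pon
    pon_to_nh4 = p.r_pon_nh4 * pon
    don_to_nh4 = p.r_don_nh4 * don
    nitrif = p.r_nitrif * nh4
    diss = p.r_opal_diss * opal
    return {
        "PON": -(to_don + pon_to_nh4),
        "DON": to_don - don_to_nh4,
        "NH4": pon_to_nh4 + don_to_nh4 - nitrif,
        "NO3": nitrif,
        "Opal": -diss,
        "SiOH4": diss,
    }


def biology_processes() -> Tuple[Process, ...]:
    """The pointwise process set with declared read/write footprints."""
    return (
        Process(
            "ps_growth",
            reads=("PS", "NO3", "NH4", IRRADIANCE),
            writes=("PS", "NO3", "NH4", "DON"),
            tendency=_ps_growth,
        ),
        Process(
            "pl_growth",
            reads=("PL", "NO3", "NH4", "SiOH4", IRRADIANCE),
            writes=("PL", "NO3", "NH4", "DON", "SiOH4"),
            tendency=_pl_growth,
        ),
        Process(
            "grazing",
            reads=("PS", "PL", "ZS", "ZL", "ZP"),
            writes=("PS", "PL", "ZS", "ZL", "ZP", "NH4", "PON", "Opal"),
            tendency=_grazing,
        ),
        Process(
            "mortality",
            reads=("PS", "PL", "ZS", "ZL", "ZP"),
            writes=("PS", "PL", "ZS", "ZL", "ZP", "PON", "Opal"),
            tendency=_mortality,
        ),
        Process(
            "remineralization",
            reads=("PON", "DON", "NH4", "Opal"),
            writes=("PON", "DON", "NH4", "NO3", "SiOH4", "Opal"),
            tendency=_remineralization,
        ),
    )


# ---------------------------------------------------------------------------
# light attenuation (vertical-column segment)
# ---------------------------------------------------------------------------


def _light_apply(params: BgcParams, grid: ColumnGrid):
    def fn(x, layout, ctx):
        i0 = ctx.get("I0", 150.0)
        y = list(x)
        att = 0.0  # optical depth to the top of the current layer
        for k in range(layout.n_cells):
            shade = params.k_water + params.k_shade * (
                x[layout.index(k, "PS")] + x[layout.index(k, "PL")]
            )
            half = 0.5 * shade * grid.dz[k]
            y[layout.index(k, IRRADIANCE)] = i0 * dm.exp(-(att + half))
            att = att + (half + half)
        return y

    return fn


def _light_hand_adjoint(params: BgcParams, grid: ColumnGrid):
    """Analytic transpose of the irradiance map (sensitivity to PS, PL)."""

    def adj(x_in, w, layout, ctx):
        i0 = ctx.get("I0", 150.0)
        K = layout.n_cells
        # recompute irradiance at the linearization state
        irr = np.empty(K)
        att = 0.0
        for k in range(K):
            shade = params.k_water + params.k_shade * (
                x_in[layout.index(k, "PS")] + x_in[layout.index(k, "PL")]
            )
            half = 0.5 * shade * grid.dz[k]
            irr[k] = i0 * np.exp(-(att + half))
            att += 2.0 * half
        w_out = w.copy()
        for k in range(K):
            w_out[layout.index(k, IRRADIANCE)] = 0.0
        # dE_k/dP_j = -E_k * k_shade * dz_j * (1 if j<k else 0.5 if j==k)
        for j in range(K):
            acc = 0.0
            for k in range(j, K):
                weight = 0.5 if k == j else 1.0
                acc += -irr[k] * params.k_shade * grid.dz[j] * weight * w[
                    layout.index(k, IRRADIANCE)
                ]
            w_out[layout.index(j, "PS")] += acc
            w_out[layout.index(j, "PL")] += acc
        return w_out

    return adj


def make_light_segment(
    params: BgcParams, grid: ColumnGrid, use_hand_adjoint: bool = True
) -> ColumnFunctionSegment:
    return ColumnFunctionSegment(
        "light",
        reads=("PS", "PL"),
        writes=(IRRADIANCE,),
        fn=_light_apply(params, grid),
        hand_adjoint=_light_hand_adjoint(params, grid),
        use_hand_adjoint=use_hand_adjoint,
    )


# ---------------------------------------------------------------------------
# linear vertical operators: diffusion and sinking
# ---------------------------------------------------------------------------


def _diffusion_coeffs(grid: ColumnGrid):
    K = grid.n_layers
    lo = np.zeros(K)
    up = np.zeros(K)
    if K > 1:
        dzh = 0.5 * (grid.dz[:-1] + grid.dz[1:])
        flux = grid.kappa * grid.dt / dzh  # m, per unit gradient
        lo[1:] = flux / grid.dz[1:]
        up[:-1] = flux / grid.dz[:-1]
    di = 1.0 - lo - up
    return lo, di, up


def make_transport_segment(grid: ColumnGrid) -> TridiagonalSegment:
    """Explicit vertical diffusion of every prognostic variable.

    Flux form, hence the volume-weighted column total of each variable is
    conserved; the operator is self-adjoint under the volume-weighted inner
    product and its Euclidean transpose is hand-coded.
    """
    lo, di, up = _diffusion_coeffs(grid)
    return TridiagonalSegment("transport", {v: (lo, di, up) for v in VARIABLES})


def _sinking_coeffs(grid: ColumnGrid, w: float):
    K = grid.n_layers
    cfl = w * grid.dt / grid.dz
    if np.any(cfl > 1.0):
        raise StabilityError(
            f"sinking CFL number {cfl.max():.3f} > 1 for speed {w * DAY:.1f} m/day"
        )
    lo = np.zeros(K)
    lo[1:] = w * grid.dt / grid.dz[1:]
    di = 1.0 - w * grid.dt / grid.dz
    up = np.zeros(K)
    return lo, di, up


def make_sinking_segment(params: BgcParams, grid: ColumnGrid) -> TridiagonalSegment:
    """First-order upwind downward advection of PON and Opal.

    Column inventory changes only through the flux across the bottom face.
    """
    return TridiagonalSegment(
        "sinking",
        {
            "PON": _sinking_coeffs(grid, params.w_pon),
            "Opal": _sinking_coeffs(grid, params.w_opal),
        },
    )


# ---------------------------------------------------------------------------
# the composed model
# ---------------------------------------------------------------------------


class ColumnModel:
    """One-column ecosystem model with declared segments and counters.

    Composition order per step (fixed; identical in nonlinear, TLM and
    adjoint paths): transport -> light attenuation -> pointwise biology ->
    sinking.  With ``use_hand_adjoints`` (default) the linear transport and
    sinking segments and the light segment use hand-coded adjoints, and only
    the biology is differentiated with dual numbers; switching it off routes
    every segment through the dual-based footprint adjoint for
    cross-validation.
    """

    def __init__(
        self,
        params: Optional[BgcParams] = None,
        grid: Optional[ColumnGrid] = None,
        surface_irradiance=150.0,
        use_hand_adjoints: bool = True,
    ):
        self.params = params or BgcParams()
        self.grid = grid or ColumnGrid.uniform()
        self.forcing = surface_irradiance
        K = self.grid.n_layers
        self.layout = make_layout(K)
        self.layout_aug = make_layout_aug(K)
        light = make_light_segment(self.params, self.grid, use_hand_adjoints)
        transport = make_transport_segment(self.grid)
        sinking = make_sinking_segment(self.params, self.grid)
        biology = EulerProcessSegment(
            "biology", biology_processes(), self.params, self.grid.dt
        )
        self.segmented = SegmentedModel(
            self.layout,
            (transport, light, biology, sinking),
            layout_aug=self.layout_aug,
            name="nemuro_column",
            ctx={"I0": self._irradiance_at(0)},
        )
        self.model = self.segmented.as_model_function()

    # surface irradiance may be a constant or a per-step sequence
    def _irradiance_at(self, k: int) -> float:
        if np.ndim(self.forcing) == 0:
            return float(self.forcing)
        seq = np.asarray(self.forcing, float)
        return float(seq[min(k, seq.size - 1)])

    def _bind(self, step_index: int) -> ModelFunction:
        self.segmented.ctx["I0"] = self._irradiance_at(step_index)
        return self.model

    @property
    def n(self) -> int:
        return self.layout.n

    def step(self, x, step_index: int = 0) -> np.ndarray:
        model = self._bind(step_index)
        return np.array(
            [float(v) for v in model([float(v) for v in as_values(x)])]
        )

    def step_tlm(self, x, u, step_index: int = 0) -> np.ndarray:
        from .engine import evaluate_tlm

        return as_values(evaluate_tlm(self._bind(step_index), as_values(x), u))

    def step_adjoint(self, x, w, step_index: int = 0) -> np.ndarray:
        model = self._bind(step_index)
        return self.segmented.adjoint(as_values(x), as_values(w), model.counter)

    def run(self, x0, n_steps: int, check_nonneg: bool = False) -> np.ndarray:
        """Integrate; returns ``(n_steps+1, n)`` with row 0 the initial state."""
        x = as_values(x0).copy()
        if check_nonneg:
            _require_nonneg(x, self.layout)
        traj = np.empty((n_steps + 1, self.n))
        traj[0] = x
        for k in range(n_steps):
            x = self.step(x, k)
            traj[k + 1] = x
        return traj

    def chlorophyll(self, x) -> np.ndarray:
        """mg chl a m^-3 per cell via the fixed nitrogen-to-chlorophyll ratio."""
        sv = StateVector(self.layout, as_values(x))
        return self.params.chl_ratio * (sv.var("PS") + sv.var("PL"))

    def total_nitrogen(self, x) -> np.ndarray:
        sv = StateVector(self.layout, as_values(x))
        return sum(sv.var(v) for v in NITROGEN_POOLS)

    def total_silicon(self, x) -> np.ndarray:
        sv = StateVector(self.layout, as_values(x))
        return sv.var("SiOH4") + sv.var("Opal") + self.params.r_si_n * sv.var("PL")


def _require_nonneg(values: np.ndarray, layout: Layout) -> None:
    bad = np.flatnonzero(np.asarray(values) < 0.0)
    if bad.size:
        cell, var = layout.unravel(int(bad[0]))
        raise NegativeStateError(
            f"negative concentration {values[bad[0]]:.4g} for {var!r} in cell "
            f"{cell} ({bad.size} negative entries total)"
        )


# ---------------------------------------------------------------------------
# standalone operations on StateVector (the scripting interface)
# ---------------------------------------------------------------------------


def light_attenuation(state: StateVector, params: BgcParams,
                      surface_irradiance: float, dz) -> np.ndarray:
    """Per-cell irradiance (W/m2) at layer mid-depths."""
    if surface_irradiance < 0:
        raise ValueError("surface irradiance must be >= 0")
    grid = ColumnGrid(np.atleast_1d(np.asarray(dz, float)),
                      dt=1.0, kappa=0.0 if np.size(dz) > 1 else None)
    layout_aug = make_layout_aug(state.layout.n_cells)
    seg = make_light_segment(params, grid)
    x = [0.0] * layout_aug.n
    for cell in range(state.layout.n_cells):
        for v in VARIABLES:
            x[layout_aug.index(cell, v)] = state.get(cell, v)
    out = seg.apply(x, layout_aug, {"I0": float(surface_irradiance)})
    return np.array(
        [float(out[layout_aug.index(k, IRRADIANCE)])
         for k in range(state.layout.n_cells)]
    )


def bgc_source_step(state: StateVector, params: BgcParams, light,
                    dt: float) -> StateVector:
    """Forward-Euler update by the summed pointwise process tendencies.

    ``light`` is the per-cell irradiance (W/m2).  Rejects negative input
    concentrations; conserves total nitrogen per cell exactly (transfers
    only).
    """
    _require_nonneg(state.values, state.layout)
    layout_aug = make_layout_aug(state.layout.n_cells)
    light = np.broadcast_to(np.asarray(light, float), (state.layout.n_cells,))
    x = [0.0] * layout_aug.n
    for cell in range(state.layout.n_cells):
        for v in VARIABLES:
            x[layout_aug.index(cell, v)] = state.get(cell, v)
        x[layout_aug.index(cell, IRRADIANCE)] = float(light[cell])
    seg = EulerProcessSegment("biology", biology_processes(), params, dt)
    y = seg.apply(x, layout_aug, {})
    out = StateVector(state.layout)
    for cell in range(state.layout.n_cells):
        for v in VARIABLES:
            out.set(cell, v, float(y[layout_aug.index(cell, v)]))
    return out


def sinking_step(state: StateVector, params: BgcParams, grid: ColumnGrid,
                 dt: Optional[float] = None):
    """Upwind sinking of PON and Opal; returns ``(new_state, bottom_flux)``.

    ``bottom_flux`` maps variable -> flux through the bottom face
    (mmol m^-2 s^-1); the column inventory change equals ``-flux * dt``.
    """
    if dt is not None and dt != grid.dt:
        grid = ColumnGrid(grid.dz, grid.kappa, dt)
    seg = make_sinking_segment(params, grid)
    layout = state.layout
    y = seg.apply(list(state.values), layout, {})
    flux = {
        "PON": params.w_pon * state.get(layout.n_cells - 1, "PON"),
        "Opal": params.w_opal * state.get(layout.n_cells - 1, "Opal"),
    }
    return StateVector(layout, [float(v) for v in y]), flux


def transport_step(state: StateVector, grid: ColumnGrid,
                   dt: Optional[float] = None) -> StateVector:
    """Explicit vertical diffusion of every variable (linear, self-adjoint
    under the volume-weighted inner product)."""
    if dt is not None and dt != grid.dt:
        grid = ColumnGrid(grid.dz, grid.kappa, dt)
    seg = make_transport_segment(grid)
    y = seg.apply(list(state.values), state.layout, {})
    return StateVector(state.layout, [float(v) for v in y])


def model_step(state: StateVector, params: BgcParams, grid: ColumnGrid,
               surface_irradiance: float = 150.0) -> StateVector:
    """One full composed step: transport -> light -> biology -> sinking."""
    model = ColumnModel(params, grid, surface_irradiance)
    return StateVector(state.layout, model.step(state.values))


def chlorophyll_diagnostic(state: StateVector, params: BgcParams) -> np.ndarray:
    """Chlorophyll a (mg m^-3) = chl_ratio * (PS + PL) per cell."""
    return params.chl_ratio * (state.var("PS") + state.var("PL"))


def default_initial_state(grid: ColumnGrid) -> StateVector:
    """A plausible stratified spring profile (surface bloom, deep nutrients)."""
    K = grid.n_layers
    z = np.cumsum(grid.dz) - 0.5 * grid.dz  # mid-layer depths
    layout = make_layout(K)
    taper = np.exp(-z / 25.0)      # biology concentrated near the surface
    enrich = 1.0 + z / 50.0        # nutrients increase with depth
    return StateVector.from_profiles(layout, {
        "PS": 0.30 * taper + 0.02,
        "PL": 0.20 * taper + 0.02,
        "ZS": 0.15 * taper + 0.01,
        "ZL": 0.10 * taper + 0.01,
        "ZP": 0.05 * taper + 0.01,
        "NO3": 8.0 * enrich,
        "NH4": 0.30 * taper + 0.05,
        "DON": 1.0 * np.ones(K),
        "PON": 0.50 * taper + 0.05,
        "SiOH4": 12.0 * enrich,
        "Opal": 0.50 * taper + 0.05,
    })
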