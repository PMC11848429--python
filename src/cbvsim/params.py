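"""Parameter set, reaction topology and run settings.

The model couples four microbial species (A--D) to a three-variant nutrient
cycle (the J-cycle) and a slower climate-like X-cycle.  All tunable constants
live in :class:`ModelParams`; per-run settings (step count, seed, initial
conditions) live in :class:`RunConfig`.  Configs are flat YAML key/value
documents whose keys mirror the dataclass field names exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "ReactionTopology",
    "RunConfig",
    "SPECIES",
    "default_params",
    "default_topology",
    "validate",
    "load_config",
    "save_config",
    "resolved_metadata",
]

#: Species identifiers, in fixed update order.
SPECIES = ("A", "B", "C", "D")


@dataclass
class ModelParams:
    """All model constants.

    Units: nutrient levels are in "units of J", the X-cycle variables in
    "units of X"; rates are per biological timestep unless noted.  The
    defaults reproduce the standard configuration of the model; the X-cycle
    influx/outflux constants and initial reservoir size, which the core
    configuration leaves open, carry documented defaults chosen so that the
    abiotic X steady state (Xin0/Xout0 = 1) sits below both the feedback
    onset ``Xon`` and the suppression threshold ``Xsuppress`` -- without
    biological byproducts, suppression can never activate.
    """

    # --- J-cycle ---
    Fin0: float = 1.0      # abiotic influx of each J-variant per timestep
    Fout0: float = 1.0     # abiotic removal rate constant (per timestep)
    Rmax: float = 1.0      # maximum interconversion rate (J per timestep)
    Km: float = 1.0        # half-saturation level (units of J)
    Ji0: float = 1.0       # normalization level for cycling ratios
    eps_X: float = 0.5     # fraction of J diverted to the X-cycle by reactions A and B

    # --- biology ---
    K: float = 1000.0      # carrying capacity per species (individuals)
    rn_bar: float = 1e-3   # substrate-availability enhancement per individual (= 1/K)
    g0: float = 1.0        # baseline population growth rate (per timestep)
    W0: float = 1.0        # baseline absolute fitness (offspring/individual/timestep)
    s: float = 0.01        # fitness sensitivity of the p-genotype to substrate level
    m0: float = 0.1        # baseline mutation probability per reproductive event
    omega: float = 1.0     # maximum bioavailable substrate fraction

    # --- X-cycle ---
    Xrel0: float = 1.0         # reservoir release rate constant
    Xfeedback0: float = 3.0    # bistable feedback amplitude
    Xon: float = 3.0           # lower threshold of the unstable region
    Xoff: float = 6.0          # upper threshold of the unstable region
    a: float = 10.0            # feedback sigmoid steepness (lower edge)
    b: float = 10.0            # feedback sigmoid steepness (upper edge)
    Xvar0: float = 1.0         # baseline byproduct-reaction efficiency
    Xin0: float = 1.0          # X influx constant
    Xout0: float = 1.0         # X (and XA/XB) removal rate constant
    Xres_init: float = 5.0     # initial solid-state reservoir size
    # Depletion cutoff: reservoir level below which it counts as exhausted
    # (the residual then moves to the transition pool in bulk).  Calibrated
    # jointly with Xres_init so that, at default activity, exhaustion falls
    # inside the default horizon for tau_X = 10 but beyond it for tau_X = 20.
    xres_eps: float = 3.0

    # --- coupling / suppression ---
    Xsuppress: float = 3.5     # X level at which suppression becomes nonzero
    alpha0: float = 1.0        # baseline suppression magnitude
    k_alpha: float = 20.0      # suppression sigmoid steepness

    # --- timescales & noise ---
    tau_J: float = 2.0         # J-cycle clock ratio (J runs tau_J times slower than biology)
    tau_X: float = 10.0        # X-cycle clock ratio (relative to the J-cycle)
    sigma_bar: float = 1.0     # overall stochastic sensitivity; 0 = deterministic mode

    # --- documented interpretation switches (defaults = adopted readings) ---
    # Growth law: True -> g0*M*(1-M/K)*|1-M/K| (square outside, restoring
    # sign above K); False -> g0*M*(1-(M/K)^2).  The square-outside form is
    # the default because its per-capita growth stays below g0 at low
    # density, which lets a near-unit suppression rate drive species C
    # extinct; under the other reading the density term vanishes at small M
    # and suppression stalls.
    growth_square_outside: bool = True
    # Reproductive events: False -> RE = round(W*freq) as printed;
    # True -> RE = round(W*freq*M) (population-scaled variant).
    re_scale_by_population: bool = False
    # Biological diffusion coefficient: False -> root-sum of the two genotypes'
    # binomial variance rates; True -> their literal product.
    gs_literal_product: bool = False


@dataclass(frozen=True)
class ReactionTopology:
    """Which J-variant each species consumes and produces.

    The wiring is fixed: A converts J1->J2, B converts J2->J1, C converts
    J1->J3 and D converts J3->J2, so the two overlapping recycling pathways
    (cycle-biota variants) are AB (J1<->J2) and CDB (J1->J3->J2->J1).
    """

    substrate: dict[str, int] = field(
        default_factory=lambda: {"A": 1, "B": 2, "C": 1, "D": 3}
    )
    product: dict[str, int] = field(
        default_factory=lambda: {"A": 2, "B": 1, "C": 3, "D": 2}
    )


@dataclass
class RunConfig:
    """Per-run settings: horizon, seed, cadence and initial conditions.

    ``None`` initial values fall back to the standard start: every species at
    carrying capacity with both genotypes equally frequent, nutrient and X
    pools at their abiotic equilibria, byproduct pools empty, and the full
    reservoir unreleased.
    """

    n_bio_steps: int = 2000
    dt_bio: float = 1.0
    seed: int = 0
    record_every: int = 1
    sigma_bar_override: float | None = None  # overrides ModelParams.sigma_bar when set
    M_init: float | None = None     # default: K
    p_init: float = 0.5
    J_init: float | None = None     # default: Fin0/Fout0
    X_init: float | None = None     # default: Xin0/Xout0
    XA_init: float = 0.0
    XB_init: float = 0.0
    Xres2_init: float = 0.0


def default_params() -> ModelParams:
    """Return the default parameter set."""
    return ModelParams()


def default_topology() -> ReactionTopology:
    return ReactionTopology()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_UNIT_INTERVAL = ("m0", "eps_X", "omega", "alpha0", "Xvar0")
_NON_NEGATIVE = (
    "Fin0", "Fout0", "Rmax", "Km", "Ji0", "g0", "W0", "Xrel0", "Xfeedback0",
    "Xon", "Xoff", "a", "b", "Xin0", "Xout0", "Xres_init", "xres_eps",
    "Xsuppress", "k_alpha", "sigma_bar", "rn_bar",
)


def validate(params: ModelParams) -> list[str]:
    """Check every parameter invariant; return a list of violation messages.

    An empty list means the parameter set is valid.  Violations are returned
    rather than raised so callers can report all of them at once.
    """
    v: list[str] = []
    for name in _NON_NEGATIVE:
        if getattr(params, name) < 0:
            v.append(f"{name} must be >= 0, got {getattr(params, name)}")
    for name in _UNIT_INTERVAL:
        val = getattr(params, name)
        if not 0.0 <= val <= 1.0:
            v.append(f"{name} must lie in [0, 1], got {val}")
    if params.K < 1:
        v.append(f"K must be >= 1, got {params.K}")
    if params.tau_J < 1:
        v.append(f"tau_J must be >= 1, got {params.tau_J}")
    if params.tau_X < 1:
        v.append(f"tau_X must be >= 1, got {params.tau_X}")
    if not params.Xon < params.Xoff:
        v.append(f"Xon must be < Xoff, got Xon={params.Xon}, Xoff={params.Xoff}")
    return v


def validate_run(run: RunConfig) -> list[str]:
    v: list[str] = []
    if run.n_bio_steps < 1:
        v.append(f"n_bio_steps must be >= 1, got {run.n_bio_steps}")
    if run.dt_bio <= 0:
        v.append(f"dt_bio must be > 0, got {run.dt_bio}")
    if run.record_every < 1:
        v.append(f"record_every must be >= 1, got {run.record_every}")
    if not 0.0 <= run.p_init <= 1.0:
        v.append(f"p_init must lie in [0, 1], got {run.p_init}")
    return v


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}
_RUN_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _coerce(name: str, value, kind):
    if kind is bool:
        if isinstance(value, bool):
            return value
        raise ValueError(f"config key {name!r}: expected a boolean, got {value!r}")
    if value is None:
        return None
    if isinstance(value, bool):
        raise ValueError(f"config key {name!r}: expected a number, got a boolean")
    return kind(value)


def load_config(path: str | Path) -> tuple[ModelParams, RunConfig]:
    """Load a flat YAML config; unspecified keys fall back to defaults.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for an
    unknown key (named in the message) or for a value that violates a
    parameter invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a flat key/value mapping")

    params = default_params()
    run = RunConfig()
    for key, value in raw.items():
        if key in _PARAM_FIELDS:
            f = _PARAM_FIELDS[key]
            kind = bool if f.type == "bool" else float
            setattr(params, key, _coerce(key, value, kind))
        elif key in _RUN_FIELDS:
            if key in ("n_bio_steps", "seed", "record_every"):
                setattr(run, key, int(value))
            else:
                setattr(run, key, _coerce(key, value, float))
        else:
            raise ValueError(f"unknown config key: {key!r}")

    violations = validate(params) + validate_run(run)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    return params, run


def save_config(path: str | Path, params: ModelParams, run: RunConfig | None = None) -> None:
    """Serialize a parameter set (and optionally run settings) to flat YAML."""
    doc: dict = dataclasses.asdict(params)
    if run is not None:
        doc.update(dataclasses.asdict(run))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def resolved_metadata(params: ModelParams, run: RunConfig) -> dict:
    """JSON-ready metadata echoing the fully resolved configuration."""
    from . import __version__

    return {
        "package": "cbvsim",
        "version": __version__,
        "params": dataclasses.asdict(params),
        "run": dataclasses.asdict(run),
        "noise_increment": "sigma_bar * g * sqrt(dt_sub) * N(0,1)",
    }


def write_metadata(path: str | Path, params: ModelParams, run: RunConfig) -> None:
    Path(path).write_text(json.dumps(resolved_metadata(params, run), indent=2))
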