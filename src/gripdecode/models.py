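"""First-order linear dynamic models with dead time mapping band power to force.

Eight model structures are supported, differing in which band-power inputs
they use (theta/alpha, beta, gamma), whether the inputs share one first-order
lag and dead time or each drive their own branch, and whether gains are tied
(the gamma-minus-beta difference model).  Each branch is the classic
``Kp / (Tp*s + 1) * exp(-Td*s)`` transfer function:  ``Kp`` is the
steady-state gain, ``Tp`` the time constant, ``Td`` the pure input-output
delay.  The time-domain equivalent of a single branch is::

    F(t) + Tp * dF/dt = Kp * u(t - Td)

Forward simulation uses the exact zero-order-hold discretisation of that
ODE; parameter estimation is bounded nonlinear least squares with a
deterministic multi-start grid over the dead time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from gripdecode.exceptions import InputError, ParameterError, UnidentifiableError

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODELS",
    "get_model",
    "count_free_parameters",
    "combine_inputs",
    "simulate_forward",
    "time_domain_oracle",
    "fit_model",
    "params_to_dict",
    "DEFAULT_BOUNDS",
]

BAND_NAMES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate decoding model.

    Attributes
    ----------
    model_id : int
        Registry id, 1..8.
    inputs : tuple of str
        Band names the model consumes.
    structure : str
        ``"differenced"`` (gamma-beta through one lag), ``"shared_lag"``
        (per-band gains, one shared lag + delay) or ``"per_band_lag"``
        (independent branch per band).
    param_names : tuple of str
        Order of the free-parameter vector.
    """

    model_id: int
    inputs: tuple[str, ...]
    structure: str
    param_names: tuple[str, ...]

    @property
    def k(self) -> int:
        """Number of free parameters (the BIC penalty count)."""
        return len(self.param_names)


def _spec(model_id, inputs, structure, param_names):
    return ModelSpec(model_id, tuple(inputs), structure, tuple(param_names))


#: Registry of the eight model structures.  Parameter-vector layouts:
#: differenced / single-band: (Kp, Tp, Td); shared_lag: per-band gains in
#: input order then (Tp, Td); per_band_lag: (Kp_i, Tp_i, Td_i) per input.
MODELS: dict[int, ModelSpec] = {
    1: _spec(1, ("gamma", "beta"), "differenced", ("Kp", "Tp", "Td")),
    2: _spec(2, ("gamma", "beta"), "shared_lag", ("Kp1", "Kp2", "Tp", "Td")),
    3: _spec(3, ("gamma", "beta"), "per_band_lag",
             ("Kp1", "Tp1", "Td1", "Kp2", "Tp2", "Td2")),
    4: _spec(4, ("gamma", "beta", "alpha"), "shared_lag",
             ("Kp1", "Kp2", "Kp3", "Tp", "Td")),
    5: _spec(5, ("gamma", "beta", "alpha"), "per_band_lag",
             ("Kp1", "Tp1", "Td1", "Kp2", "Tp2", "Td2", "Kp3", "Tp3", "Td3")),
    6: _spec(6, ("alpha",), "differenced", ("Kp", "Tp", "Td")),
    7: _spec(7, ("beta",), "differenced", ("Kp", "Tp", "Td")),
    8: _spec(8, ("gamma",), "differenced", ("Kp", "Tp", "Td")),
}

#: Per-parameter-kind optimisation bounds.
DEFAULT_BOUNDS = {"Kp": (-100.0, 100.0), "Tp": (0.01, 5.0), "Td": (0.0, 0.5)}


def get_model(model_id: int) -> ModelSpec:
    try:
        return MODELS[int(model_id)]
    except (KeyError, TypeError) as exc:
        raise InputError(f"unknown model id {model_id!r}; valid ids are 1..8") from exc


def count_free_parameters(spec: ModelSpec | int) -> int:
    """Free-parameter count ``k`` used in the BIC penalty."""
    if not isinstance(spec, ModelSpec):
        spec = get_model(spec)
    return spec.k


def params_to_dict(spec: ModelSpec, params: Sequence[float]) -> dict[str, float]:
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.k,):
        raise ParameterError(
            f"model {spec.model_id} expects {spec.k} parameters, got {params.shape}"
        )
    return dict(zip(spec.param_names, params.tolist()))


def _as_band_dict(trace) -> dict[str, np.ndarray]:
    """Accept a BandPowerTrace-like object or a mapping of band -> array."""
    if isinstance(trace, Mapping):
        return {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in trace.items()}
    out = {}
    for band in BAND_NAMES:
        if hasattr(trace, band):
            out[band] = np.atleast_2d(np.asarray(getattr(trace, band), dtype=float))
    return out


def combine_inputs(spec: ModelSpec, trace, params: Sequence[float]):
    """Build the per-branch inputs ``(gain, u, Tp, Td)`` for a model.

    ``trace`` may be a :class:`~gripdecode.features.BandPowerTrace`, or a
    mapping band name -> array of shape ``(n_samples,)`` or
    ``(n_trials, n_samples)``.  Returns a list of branches, each a tuple of
    the branch gain, the (pre-gain) input array, time constant and dead time.
    """
    bands = _as_band_dict(trace)
    missing = [b for b in spec.inputs if b not in bands]
    if missing:
        raise InputError(f"model {spec.model_id} needs band(s) {missing} not in trace")
    p = params_to_dict(spec, params)

    if spec.structure == "differenced":
        if spec.inputs == ("gamma", "beta"):
            u = bands["gamma"] - bands["beta"]
        else:  # single band (models 6-8)
            u = bands[spec.inputs[0]]
        return [(p["Kp"], u, p["Tp"], p["Td"])]
    if spec.structure == "shared_lag":
        gains = [p[f"Kp{i + 1}"] for i in range(len(spec.inputs))]
        u = sum(g * bands[b] for g, b in zip(gains, spec.inputs))
        return [(1.0, u, p["Tp"], p["Td"])]
    if spec.structure == "per_band_lag":
        return [
            (p[f"Kp{i + 1}"], bands[b], p[f"Tp{i + 1}"], p[f"Td{i + 1}"])
            for i, b in enumerate(spec.inputs)
        ]
    raise InputError(f"unknown structure {spec.structure!r}")


def _fractional_delay(u: np.ndarray, delay_samples: float) -> np.ndarray:
    """Shift along the last axis by a (possibly fractional) number of samples.

    Linear interpolation between neighbouring samples keeps the dead time a
    continuous optimisation variable; the signal is zero-padded on the left
    (rest before the window).
    """
    if delay_samples < 0:
        raise ParameterError("negative dead time")
    n = u.shape[-1]
    i0 = int(np.floor(delay_samples))
    frac = delay_samples - i0
    if i0 >= n:
        raise ParameterError(
            f"dead time of {delay_samples} samples exceeds trace length {n}"
        )

    def shift(k):
        if k == 0:
            return u
        if k >= n:
            return np.zeros_like(u)
        pad = np.zeros(u.shape[:-1] + (k,), dtype=float)
        return np.concatenate([pad, u[..., : n - k]], axis=-1)

    if frac == 0.0:
        return shift(i0)
    return (1.0 - frac) * shift(i0) + frac * shift(i0 + 1)


def _first_order_lag(u: np.ndarray, fs: float, tp: float) -> np.ndarray:
    """Exact zero-order-hold discretisation of ``y + Tp y' = u`` from rest."""
    if tp <= 0:
        raise ParameterError("time constant Tp must be > 0")
    a = float(np.exp(-1.0 / (fs * tp)))
    return lfilter([1.0 - a], [1.0, -a], u, axis=-1)


def simulate_forward(
    spec: ModelSpec | int,
    params: Sequence[float],
    trace,
    fs_feature: float,
    clamp: bool = True,
) -> np.ndarray:
    """Predict force from band-power inputs.

    Each branch applies the dead time (continuous shift, linear
    interpolation), the exact ZOH first-order lag and the branch gain;
    branch outputs are summed.  The initial condition is zero (rest before
    the window).  With ``clamp=True`` the output is floored at zero, as done
    for final force predictions; fitting uses the unclamped output.
    """
    if not isinstance(spec, ModelSpec):
        spec = get_model(spec)
    branches = combine_inputs(spec, trace, params)
    if isinstance(trace, Mapping):
        in_ndim = max(np.ndim(trace[b]) for b in spec.inputs if b in trace)
    else:
        in_ndim = max(
            np.ndim(getattr(trace, b)) for b in spec.inputs if getattr(trace, b, None) is not None
        )
    out = None
    for gain, u, tp, td in branches:
        if td < 0:
            raise ParameterError("dead time Td must be >= 0")
        if u.shape[-1] < 2:
            raise InputError("trace must contain at least 2 samples")
        u_d = _fractional_delay(u, td * fs_feature)
        y = gain * _first_order_lag(u_d, fs_feature, tp)
        out = y if out is None else out + y
    if clamp:
        out = np.maximum(out, 0.0)
    return out[0] if in_ndim == 1 else out


def time_domain_oracle(
    spec: ModelSpec | int,
    params: Sequence[float],
    trace,
    fs_feature: float,
    substeps: int = 20,
    clamp: bool = True,
) -> np.ndarray:
    """Independent force prediction by fixed-step RK4 integration of the ODE.

    Integrates ``F' = (Kp * u(t - Td) - F) / Tp`` per branch with
    ``substeps`` RK4 steps per feature sample, using the zero-order-hold
    input (held delayed samples).  Serves as an oracle for
    :func:`simulate_forward`; only 1-D traces are supported.
    """
    if not isinstance(spec, ModelSpec):
        spec = get_model(spec)
    branches = combine_inputs(spec, trace, params)
    n = branches[0][1].shape[-1]
    dt = 1.0 / fs_feature
    h = dt / substeps
    total = np.zeros(n)
    for gain, u, tp, td in branches:
        if tp <= 0 or td < 0:
            raise ParameterError("require Tp > 0 and Td >= 0")
        u1 = np.asarray(u, dtype=float).reshape(-1)
        u_d = _fractional_delay(u1[None, :], td * fs_feature)[0]
        y = np.zeros(n)
        state = 0.0
        # sample i's input is held over the interval ENDING at t_i, so the
        # first integration interval is (-dt, 0] with input u_d[0]
        for i in range(n):
            u_c = u_d[i]
            for _ in range(substeps):
                k1 = (u_c - state) / tp
                k2 = (u_c - (state + h / 2 * k1)) / tp
                k3 = (u_c - (state + h / 2 * k2)) / tp
                k4 = (u_c - (state + h * k3)) / tp
                state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            y[i] = state
        total += gain * y
    if clamp:
        total = np.maximum(total, 0.0)
    return total


@dataclass
class FitResult:
    """Outcome of least-squares identification of one model."""

    spec: ModelSpec
    params: np.ndarray
    training_sse: float
    n_obs: int
    converged: bool
    n_starts_used: int
    param_dict: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.param_dict:
            self.param_dict = params_to_dict(self.spec, self.params)

    def to_json_dict(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "params": self.param_dict,
            "sse": self.training_sse,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "feature_convention": "fractional power change (0 = baseline)",
        }


def _bounds_for(spec: ModelSpec):
    lo, hi = [], []
    for name in spec.param_names:
        kind = "Kp" if name.startswith("Kp") else ("Tp" if name.startswith("Tp") else "Td")
        b = DEFAULT_BOUNDS[kind]
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


#: Physiologically expected gain sign per band (beta suppresses with force).
_BAND_SIGN = {"gamma": 1.0, "beta": -1.0, "alpha": 1.0}


def _starts_for(spec: ModelSpec, td_grid, tp0=0.2):
    """Deterministic multi-start grid.

    Shared-lag structures: dead-time grid x overall gain sign, one time
    constant.  Per-band-lag structures additionally cross fast/slow time
    constants per branch (branches readily swap temporal roles otherwise)
    and start gains at the physiologically expected signs and their flip.
    """
    starts = []
    if spec.structure != "per_band_lag":
        for td0 in td_grid:
            for sign in (1.0, -1.0):
                x0 = []
                for name in spec.param_names:
                    if name.startswith("Kp"):
                        x0.append(sign * 1.0)
                    elif name.startswith("Tp"):
                        x0.append(tp0)
                    else:
                        x0.append(td0)
                starts.append(np.array(x0))
        return starts
    nb = len(spec.inputs)
    for tp_pattern in itertools.product((0.1, 0.4), repeat=nb):
        for td0 in (0.05, 0.3):
            for flip in (1.0, -1.0):
                x0 = []
                for j, band in enumerate(spec.inputs):
                    x0 += [flip * _BAND_SIGN[band], tp_pattern[j], td0]
                starts.append(np.array(x0))
    return starts


def _stack_trials(traces, forces):
    """Normalise (traces, forces) into band dict of (n_trials, n) + force array."""
    if isinstance(traces, (list, tuple)):
        bands: dict[str, np.ndarray] = {}
        for band in BAND_NAMES:
            rows = [np.asarray(getattr(t, band), dtype=float) for t in traces
                    if getattr(t, band, None) is not None]
            if rows:
                bands[band] = np.vstack(rows)
    else:
        bands = _as_band_dict(traces)
    force = np.atleast_2d(np.asarray(forces, dtype=float))
    n = force.shape[-1]
    for band, arr in bands.items():
        if arr.shape[-1] != n:
            raise InputError(
                f"band {band!r} has {arr.shape[-1]} samples but force has {n}"
            )
    return bands, force


def fit_model(
    spec: ModelSpec | int,
    traces,
    forces,
    fs_feature: float,
    td_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
    max_nfev: int | None = None,
) -> FitResult:
    """Identify model parameters by bounded nonlinear least squares.

    Minimises the sum of squared errors between unclamped predictions and
    the measured force over all training trials concatenated.  A fixed
    multi-start grid (dead times x gain signs) guards against local minima;
    the best-SSE start wins.  Clamping at zero is applied only to final
    predictions, never inside the objective, keeping it smooth.
    """
    if not isinstance(spec, ModelSpec):
        spec = get_model(spec)
    bands, force = _stack_trials(traces, forces)
    sub = {b: bands[b] for b in spec.inputs}
    if all(np.allclose(a, 0.0) for a in sub.values()):
        raise UnidentifiableError(
            f"all input features for model {spec.model_id} are identically zero"
        )
    n_obs = force.size
    if n_obs <= spec.k:
        raise InputError(f"need more than k={spec.k} observations, got {n_obs}")

    lo, hi = _bounds_for(spec)

    def residual(theta):
        pred = simulate_forward(spec, theta, sub, fs_feature, clamp=False)
        return (pred - force).ravel()

    scan_cap = max_nfev if max_nfev is not None else 200
    best = None
    n_starts = 0
    for x0 in _starts_for(spec, td_grid):
        n_starts += 1
        res = least_squares(
            residual, np.clip(x0, lo, hi), bounds=(lo, hi),
            method="trf", max_nfev=scan_cap,
        )
        if best is None or res.cost < best.cost:
            best = res
    # polish the winning start without the scan iteration cap
    best = least_squares(
        residual, best.x, bounds=(lo, hi), method="trf", max_nfev=max_nfev
    )
    sse = float(2.0 * best.cost)  # least_squares cost = 0.5 * SSE
    return FitResult(
        spec=spec,
        params=best.x.copy(),
        training_sse=sse,
        n_obs=n_obs,
        converged=bool(best.status > 0),
        n_starts_used=n_starts,
    )
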