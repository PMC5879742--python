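"""Cole impedance models: evaluation and bounded least-squares fitting.

The Cole model is the workhorse empirical description of skin-electrode
contact impedance.  A single dispersion reads

    Z(w) = R_inf + R1 / (1 + R1 * C1 * (j w)**alpha1),      w = 2 pi f

with ``0 < alpha1 <= 1``.  The fractional exponent models the constant-phase
element of the interface; ``alpha = 1`` reduces the dispersion term exactly to
a parallel RC circuit.  A second dispersion adds another term of the same
form.  Note the time-constant convention: the literature is split between
``tau**alpha = R*C`` and ``tau = (R*C)**(1/alpha)``; this module fixes
``Z_disp = R / (1 + R*C*(jw)**alpha)`` because it nests the RC circuit
without reinterpreting ``C``.

Fitting follows the estimator/results idiom: build a :class:`ColeModel` from
an :class:`~texelec.impedance.ImpedanceSpectrum` (or raw arrays), call
:meth:`ColeModel.fit`, and inspect the returned :class:`ColeResults` —
parameter estimates, asymptotic standard errors, residual diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .impedance import ImpedanceSpectrum

__all__ = ["Dispersion", "ColeParameters", "cole_eval", "ColeModel", "ColeResults"]


@dataclass(frozen=True)
class Dispersion:
    """One Cole dispersion term ``R / (1 + R*C*(jw)**alpha)``."""

    r: float  # ohm
    c: float  # farad
    alpha: float  # dimensionless, (0, 1]

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("dispersion resistance must be > 0")
        if not self.c > 0:
            raise ValueError("dispersion capacitance must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class ColeParameters:
    """High-frequency resistance plus one or two dispersions."""

    r_inf: float  # ohm
    dispersions: tuple[Dispersion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.r_inf < 0:
            raise ValueError("r_inf must be >= 0")
        if not 1 <= len(self.dispersions) <= 2:
            raise ValueError("need 1 or 2 dispersions")
        object.__setattr__(self, "dispersions", tuple(self.dispersions))

    @property
    def r_zero(self) -> float:
        """Low-frequency (DC) resistance, ``R_inf + sum R_k``."""
        return self.r_inf + sum(d.r for d in self.dispersions)

    @classmethod
    def single(cls, r_inf: float, r: float, c: float, alpha: float) -> "ColeParameters":
        return cls(r_inf, (Dispersion(r, c, alpha),))

    def to_dict(self) -> dict:
        return {
            "r_inf": self.r_inf,
            "dispersions": [
                {"r": d.r, "c": d.c, "alpha": d.alpha} for d in self.dispersions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColeParameters":
        return cls(
            float(d["r_inf"]),
            tuple(Dispersion(x["r"], x["c"], x["alpha"]) for x in d["dispersions"]),
        )


def cole_eval(params: ColeParameters, frequencies) -> ImpedanceSpectrum:
    """Evaluate the Cole impedance on a frequency grid.

    Zero frequency is allowed and returns the analytic limit ``R_inf + sum
    R_k`` (the fractional power is otherwise evaluated on the principal
    branch, ``(jw)**alpha = w**alpha * exp(j alpha pi / 2)``).
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be >= 0")
    w = 2.0 * np.pi * f
    z = np.full(f.shape, complex(params.r_inf), dtype=complex)
    for d in params.dispersions:
        with np.errstate(divide="ignore", invalid="ignore"):
            jw_alpha = np.where(
                w > 0,
                w**d.alpha * np.exp(1j * d.alpha * np.pi / 2.0),
                0.0,
            )
        z = z + d.r / (1.0 + d.r * d.c * jw_alpha)
    return ImpedanceSpectrum(f, z, label="cole_model")


def _pack(params: ColeParameters) -> np.ndarray:
    """Internal parameterization: log10 for the scale parameters, alpha raw."""
    x = [np.log10(max(params.r_inf, 1e-12))]
    for d in params.dispersions:
        x += [np.log10(d.r), np.log10(d.c), d.alpha]
    return np.asarray(x)


def _unpack(x: np.ndarray) -> ColeParameters:
    n_disp = (len(x) - 1) // 3
    disps = tuple(
        Dispersion(10.0 ** x[1 + 3 * k], 10.0 ** x[2 + 3 * k], float(x[3 + 3 * k]))
        for k in range(n_disp)
    )
    return ColeParameters(10.0 ** x[0], disps)


class ColeModel:
    """Cole impedance model to be fitted to a measured spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Measured complex impedance versus frequency.
    n_dispersions : {1, 2}
        Number of dispersion terms.
    mode : {"magnitude", "complex"}
        Fit objective: least squares on ``log10 |Z|`` (default, matching how
        contact-impedance data are usually presented on a Bode magnitude
        plot), or on stacked real and imaginary parts.

    Notes
    -----
    The span requirements guard identifiability: a single dispersion needs at
    least 5 frequencies over 2 decades, a double dispersion at least 8 over 3.
    Scale parameters are fitted in log10 space; ``alpha`` is box-bounded to
    ``(0, 1]``.
    """

    def __init__(
        self,
        spectrum: ImpedanceSpectrum,
        n_dispersions: int = 1,
        mode: str = "magnitude",
    ) -> None:
        if n_dispersions not in (1, 2):
            raise ValueError("n_dispersions must be 1 or 2")
        if mode not in ("magnitude", "complex"):
            raise ValueError("mode must be 'magnitude' or 'complex'")
        f = np.asarray(spectrum.frequencies, dtype=float)
        if np.any(f <= 0):
            raise ValueError("fitting requires strictly positive frequencies")
        n_min, decades_min = (5, 2.0) if n_dispersions == 1 else (8, 3.0)
        if f.size < n_min:
            raise ValueError(f"need at least {n_min} frequencies")
        span = np.log10(f[-1] / f[0])
        if span < decades_min:
            raise ValueError(
                f"frequency span of {span:.2f} decades is below the "
                f"{decades_min:.0f} required for {n_dispersions} dispersion(s)"
            )
        self.spectrum = spectrum
        self.n_dispersions = n_dispersions
        self.mode = mode

    @classmethod
    def from_arrays(cls, frequencies, z, **kwargs) -> "ColeModel":
        return cls(ImpedanceSpectrum(frequencies, z), **kwargs)

    # ------------------------------------------------------------------ fit

    def start_params(self) -> ColeParameters:
        """Plateau-heuristic starting values.

        ``R_inf`` starts at the high-frequency magnitude floor, the dispersion
        resistance at the plateau-to-plateau drop, ``alpha`` at 0.8 (a typical
        tissue/interface value) and ``C`` at the value that places the corner
        frequency ``1/(2 pi R C)`` at the grid's geometric midpoint.  For two
        dispersions the drop is split evenly and the corners are placed at the
        one-third points of the log-frequency span.
        """
        f = self.spectrum.frequencies
        mag = np.abs(self.spectrum.z)
        r_inf0 = max(float(mag.min()), 1e-9)
        drop = max(float(mag.max() - mag.min()), r_inf0 * 1e-3)
        if self.n_dispersions == 1:
            f_mid = float(np.sqrt(f[0] * f[-1]))
            r1 = drop
            return ColeParameters.single(r_inf0, r1, 1.0 / (2 * np.pi * f_mid * r1), 0.8)
        lf0, lf1 = np.log10(f[0]), np.log10(f[-1])
        corners = 10.0 ** np.array([lf0 + (lf1 - lf0) / 3, lf0 + 2 * (lf1 - lf0) / 3])
        disps = tuple(
            Dispersion(drop / 2, 1.0 / (2 * np.pi * fc * (drop / 2)), 0.8)
            for fc in corners
        )
        return ColeParameters(r_inf0, disps)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        z_model = cole_eval(_unpack(x), self.spectrum.frequencies).z
        if self.mode == "magnitude":
            return np.log10(np.abs(z_model)) - np.log10(np.abs(self.spectrum.z))
        d = z_model - self.spectrum.z
        scale = np.abs(self.spectrum.z)
        return np.concatenate([d.real / scale, d.imag / scale])

    def fit(self, start: ColeParameters | None = None) -> "ColeResults":
        """Bounded trust-region least squares from the plateau heuristic.

        Non-convergence is reported through ``ColeResults.converged`` rather
        than raised, so a flaky spectrum still yields inspectable diagnostics.
        """
        x0 = _pack(start if start is not None else self.start_params())
        n = self.n_dispersions
        lo = np.array([-12.0] + [-12.0, -15.0, 1e-6] * n)
        hi = np.array([12.0] + [12.0, 3.0, 1.0] * n)
        x0 = np.clip(x0, lo, hi)
        sol = optimize.least_squares(
            self._residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=20000,
        )
        params = _unpack(sol.x)
        resid = sol.fun
        dof = max(resid.size - sol.x.size, 1)
        s2 = float(resid @ resid) / dof
        # Gauss-Newton covariance in the internal (log10) parameterization
        try:
            jtj = sol.jac.T @ sol.jac
            cov = s2 * np.linalg.pinv(jtj)
            bse_internal = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            bse_internal = np.full(sol.x.size, np.nan)
        return ColeResults(
            model=self,
            params=params,
            converged=bool(sol.status > 0),
            residual_norm=float(np.linalg.norm(resid)),
            optimality=float(sol.optimality),
            nfev=int(sol.nfev),
            _x=sol.x,
            _bse_internal=bse_internal,
        )


@dataclass
class ColeResults:
    """Fit results: estimates, uncertainties and diagnostics."""

    model: ColeModel
    params: ColeParameters
    converged: bool
    residual_norm: float
    optimality: float
    nfev: int
    _x: np.ndarray
    _bse_internal: np.ndarray

    @property
    def param_names(self) -> list[str]:
        names = ["r_inf"]
        for k in range(len(self.params.dispersions)):
            i = k + 1
            names += [f"r{i}", f"c{i}", f"alpha{i}"]
        return names

    @property
    def param_values(self) -> np.ndarray:
        vals = [self.params.r_inf]
        for d in self.params.dispersions:
            vals += [d.r, d.c, d.alpha]
        return np.asarray(vals)

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors on the natural scale.

        Scale parameters are fitted as log10 values; the delta method maps
        their internal standard errors back: ``se(p) = p * ln(10) * se(log10
        p)``.  ``alpha`` is fitted directly.
        """
        vals = self.param_values
        se = np.array(self._bse_internal, dtype=float)
        out = np.empty_like(se)
        for i, name in enumerate(self.param_names):
            if name.startswith("alpha"):
                out[i] = se[i]
            else:
                out[i] = vals[i] * np.log(10.0) * se[i]
        return out

    def predict(self, frequencies=None) -> ImpedanceSpectrum:
        if frequencies is None:
            frequencies = self.model.spectrum.frequencies
        return cole_eval(self.params, frequencies)

    def summary(self) -> str:
        lines = [
            "Cole impedance model fit",
            "=" * 48,
            f"dispersions: {len(self.params.dispersions)}   "
            f"objective: {self.model.mode}",
            f"n frequencies: {self.model.spectrum.frequencies.size}   "
            f"converged: {self.converged}",
            f"residual norm: {self.residual_norm:.3e}   "
            f"first-order optimality: {self.optimality:.3e}",
            "-" * 48,
            f"{'param':>8} {'estimate':>14} {'std err':>12}",
        ]
        for name, val, se in zip(self.param_names, self.param_values, self.bse):
            lines.append(f"{name:>8} {val:>14.6g} {se:>12.3g}")
        lines.append("=" * 48)
        return "\n".join(lines)
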