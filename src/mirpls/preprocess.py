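"""Spectral pre-treatment pipelines.

Four primitive operators are supported, composable in any order:

* ``subtract_minimum`` — per-spectrum offset removal (row minimum -> 0);
* ``normalize`` — per-spectrum scaling; default min-max to [0, 1], with
  unit-vector and unit-area alternatives;
* ``derivative`` — Savitzky-Golay smoothed derivative w.r.t. wavenumber
  (order 1 or 2), full grid length preserved via polynomial extrapolation
  in the end windows;
* ``mean_center`` — per-wavenumber column centering, the only stateful
  step: column means are learned on the calibration block and re-used,
  never re-estimated, when transforming prediction samples.

The eleven named chains used for model comparison in ethanol/MIR
calibration work (all starting with minimum subtraction) are registered in
:data:`PIPELINES`; ``build_pipeline`` instantiates them by name, "raw"
giving the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateSpectrumError, PipelineError, StateError

#: Savitzky-Golay defaults: 9-point window; quadratic fit for the first
#: derivative, cubic for the second.  Finite differences would amplify the
#: instrument noise the smoothing window is there to suppress.
DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLYORDER = {1: 2, 2: 3}


class Step:
    """A pre-treatment operator. Stateless unless it overrides fit()."""

    name: str = "step"

    def fit(self, X: np.ndarray) -> "Step":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def descriptor(self) -> dict:
        return {"name": self.name}


class SubtractMinimum(Step):
    name = "subtract_minimum"

    def transform(self, X: np.ndarray) -> np.ndarray:
        return X - X.min(axis=1, keepdims=True)


class Normalize(Step):
    name = "normalize"

    def __init__(self, method: str = "minmax"):
        if method not in ("minmax", "vector", "area"):
            raise PipelineError(f"unknown normalization method {method!r}")
        self.method = method

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.method == "minmax":
            lo = X.min(axis=1, keepdims=True)
            rng = X.max(axis=1, keepdims=True) - lo
            if np.any(rng <= 0):
                raise DegenerateSpectrumError(
                    "flat spectrum: min-max normalization undefined"
                )
            return (X - lo) / rng
        if self.method == "vector":
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise DegenerateSpectrumError("zero spectrum: unit-vector norm undefined")
            return X / norms
        areas = np.abs(X).sum(axis=1, keepdims=True)
        if np.any(areas == 0):
            raise DegenerateSpectrumError("zero spectrum: unit-area norm undefined")
        return X / areas

    def descriptor(self) -> dict:
        return {"name": self.name, "method": self.method}


class Derivative(Step):
    name = "derivative"

    def __init__(
        self,
        order: int,
        window: int = DEFAULT_SG_WINDOW,
        polyorder: int | None = None,
        spacing: float = 1.0,
    ):
        if order not in (1, 2):
            raise PipelineError(f"derivative order must be 1 or 2, got {order}")
        if polyorder is None:
            polyorder = DEFAULT_SG_POLYORDER[order]
        if window % 2 == 0 or window <= polyorder or polyorder < order:
            raise PipelineError(
                f"need odd window > polyorder >= order; got window={window}, "
                f"polyorder={polyorder}, order={order}"
            )
        self.order = order
        self.window = window
        self.polyorder = polyorder
        self.spacing = spacing

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.window >= X.shape[1]:
            raise PipelineError(
                f"window {self.window} >= grid length {X.shape[1]}"
            )
        return savgol_filter(
            X,
            window_length=self.window,
            polyorder=self.polyorder,
            deriv=self.order,
            delta=self.spacing,
            axis=1,
            mode="interp",
        )

    def descriptor(self) -> dict:
        return {
            "name": self.name,
            "order": self.order,
            "window": self.window,
            "polyorder": self.polyorder,
            "spacing": self.spacing,
        }


class MeanCenter(Step):
    """Column centering. Means learned at fit time, frozen thereafter."""

    name = "mean_center"

    def __init__(self, means: np.ndarray | None = None):
        self.means = None if means is None else np.asarray(means, dtype=float)

    def fit(self, X: np.ndarray) -> "MeanCenter":
        if X.shape[0] < 2:
            raise StateError("mean centering needs at least 2 calibration samples")
        self.means = X.mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise StateError("mean_center used before fitting")
        return X - self.means

    def descriptor(self) -> dict:
        d = {"name": self.name}
        if self.means is not None:
            d["means"] = self.means.tolist()
        return d


_STEP_CLASSES = {
    "subtract_minimum": SubtractMinimum,
    "normalize": Normalize,
    "derivative": Derivative,
    "mean_center": MeanCenter,
}


@dataclass
class PretreatmentPipeline:
    """Ordered chain of pre-treatment steps with frozen calibration state.

    ``fit_transform`` learns any stateful parameters (column means) while
    transforming the calibration block; ``transform`` then applies the
    stored state to new samples without re-estimating anything, so a
    prediction spectrum is treated exactly as the calibration block was.
    """

    steps: list[Step] = field(default_factory=list)
    name: str = "custom"
    fitted: bool = False

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            X = step.fit(X).transform(X)
        self.fitted = True
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError(f"pipeline {self.name!r} used before fitting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            X = step.transform(X)
        return X

    def descriptors(self) -> list[dict]:
        return [s.descriptor() for s in self.steps]

    @classmethod
    def from_descriptors(cls, descriptors: Sequence[dict], name: str = "custom") -> "PretreatmentPipeline":
        steps: list[Step] = []
        for d in descriptors:
            d = dict(d)
            kind = d.pop("name", None)
            if kind not in _STEP_CLASSES:
                raise PipelineError(f"unknown step {kind!r}")
            if kind == "mean_center" and "means" in d:
                steps.append(MeanCenter(means=np.asarray(d["means"])))
            else:
                steps.append(_STEP_CLASSES[kind](**d))
        pipe = cls(steps=steps, name=name)
        # a pipeline whose stateful steps all carry stored state is usable as-is
        pipe.fitted = all(
            not isinstance(s, MeanCenter) or s.means is not None for s in steps
        )
        return pipe


# The eleven comparison chains (plus "raw"), operators left to right in
# application order.  d1/d2 = Savitzky-Golay 1st/2nd derivative.
PIPELINES: dict[str, tuple[str, ...]] = {
    "raw": (),
    "sub_min+1st_derivative": ("sub", "d1"),
    "sub_min+2nd_derivative+mean_centering": ("sub", "d2", "mc"),
    "sub_min+1st_derivative+mean_centering": ("sub", "d1", "mc"),
    "sub_min+normalization+1st_derivative+mean_centering": ("sub", "norm", "d1", "mc"),
    "sub_min+normalization+2nd_derivative+mean_centering": ("sub", "norm", "d2", "mc"),
    "sub_min+normalization+mean_centering": ("sub", "norm", "mc"),
    "sub_min+mean_centering": ("sub", "mc"),
    "sub_min+normalization+1st_derivative": ("sub", "norm", "d1"),
    "sub_min+normalization+2nd_derivative": ("sub", "norm", "d2"),
    "sub_min+normalization": ("sub", "norm"),
    "sub_min+2nd_derivative": ("sub", "d2"),
}


def build_pipeline(
    name: str,
    spacing: float = 1.0,
    window: int = DEFAULT_SG_WINDOW,
    normalization: str = "minmax",
) -> PretreatmentPipeline:
    """Instantiate a named pre-treatment chain.

    ``spacing`` is the wavenumber grid spacing in cm^-1, needed so
    derivatives are per-cm^-1 rather than per-index.
    """
    if name not in PIPELINES:
        raise PipelineError(
            f"unknown pipeline {name!r}; valid names: {', '.join(PIPELINES)}"
        )
    codes = PIPELINES[name]
    steps: list[Step] = []
    for code in codes:
        if code == "sub":
            steps.append(SubtractMinimum())
        elif code == "norm":
            steps.append(Normalize(method=normalization))
        elif code == "d1":
            steps.append(Derivative(1, window=window, spacing=spacing))
        elif code == "d2":
            steps.append(Derivative(2, window=window, spacing=spacing))
        elif code == "mc":
            steps.append(MeanCenter())
    pipe = PretreatmentPipeline(steps=steps, name=name)
    if not any(isinstance(s, MeanCenter) for s in steps):
        pipe.fitted = True  # stateless chain: usable without calibration state
    return pipe
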