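"""Untrained two-layer lateral-inhibition network.

The model is a 64x64 input layer (one unit per image pixel) fully connected to
a 20x20 output layer by fixed random weights w ~ N(mu=0.5, var=0.1); no
training of any kind.  Each layer performs a *single*, simultaneous pass of
subtractive lateral inhibition: every unit suppresses every other unit of its
layer by

    gain * a_{x,y}^2 * exp(-R^2 / (2 sigma_{x,y}^2)),

where ``a_{x,y}`` is the inhibiting (source) unit's pre-inhibition activity,
``R`` the Euclidean distance between the units in grid coordinates, and
``sigma_{x,y}`` the *source* unit's inhibition range.  The gain is 2: a unit
inhibits its surround twice as strongly as its own drive, keeping the network
from over-excitation.  The inhibition is *quadratic* in the source activity,
so it grows faster than the feedforward drive as stimulus intensity rises --
the property that makes the output layer collapse toward zero response under
strong, unattenuated input (for binary images the input layer is insensitive
to the square).  Inhibition ranges are heterogeneous across units, drawn once
per network from a positive-truncated Gaussian (input layer mu=0.67, sd=0.40;
output layer mu=0.26, sd=0.22, in units of the layer's own grid spacing).
Post-inhibition activities are rectified at zero by default (firing-rate
reading); ``rectify=False`` exposes the raw values.

Input-layer inhibition suppresses non-numerical features (area, shape,
perimeter) so that total input-layer output tracks item count; output-layer
inhibition differentiates units into numerosity preferences.  Either pass can
be ablated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

INPUT_SHAPE = (64, 64)
OUTPUT_SHAPE = (20, 20)

_sq_dist_cache: dict = {}


def grid_squared_distances(shape: tuple) -> np.ndarray:
    """(N, N) squared Euclidean distances between the units of a grid layer."""
    if shape not in _sq_dist_cache:
        rows, cols = np.indices(shape).reshape(2, -1).astype(float)
        d2 = (rows[:, None] - rows[None, :]) ** 2
        d2 += (cols[:, None] - cols[None, :]) ** 2
        d2.setflags(write=False)
        _sq_dist_cache[shape] = d2
    return _sq_dist_cache[shape]


def sample_sigma_field(
    shape: tuple, mu: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-unit inhibition ranges ~ N(mu, sd), redrawn until positive.

    Redrawing (rather than taking absolute values) keeps the mode of the
    field at ``mu``; the resulting law is the Gaussian truncated to (0, inf).
    """
    if mu <= 0:
        raise ValueError("sigma-field mean must be positive")
    field = rng.normal(mu, sd, size=shape)
    if sd > 0:
        bad = field <= 0
        while bad.any():
            field[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = field <= 0
    return field


class InhibitionOperator:
    """Precomputed single-pass lateral-inhibition map for one layer.

    Holds the dense unit-to-unit kernel K[target, source] =
    gain * exp(-R^2 / (2 sigma_source^2)) with a zero diagonal
    (self-exclusion), so that one inhibition pass is a single mat-vec
    against the squared activities.
    """

    def __init__(self, sigmas: np.ndarray, gain: float = 2.0):
        sigmas = np.asarray(sigmas, dtype=float)
        if (sigmas <= 0).any():
            raise ValueError("all sigma values must be positive")
        self.shape = sigmas.shape
        coef = -0.5 / sigmas.reshape(-1) ** 2
        kernel = grid_squared_distances(self.shape) * coef[None, :]
        np.exp(kernel, out=kernel)
        kernel *= gain
        np.fill_diagonal(kernel, 0.0)
        self.kernel = kernel

    def apply(self, activity: np.ndarray, rectify: bool = True) -> np.ndarray:
        activity = np.asarray(activity, dtype=float)
        if activity.shape != self.shape:
            raise ValueError(
                f"activity shape {activity.shape} != layer shape {self.shape}"
            )
        flat = activity.reshape(-1)
        out = flat - self.kernel @ (flat * flat)
        if rectify:
            np.maximum(out, 0.0, out=out)
        return out.reshape(self.shape)


def lateral_inhibition(
    activity: np.ndarray,
    sigmas: np.ndarray,
    gain: float = 2.0,
    rectify: bool = True,
) -> np.ndarray:
    """One simultaneous inhibition pass over a grid layer.

    All units inhibit one another using *pre*-inhibition activities (squared,
    scaled by ``gain``); each unit's own activity is excluded from its own
    inhibition sum.
    """
    activity = np.asarray(activity, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if activity.shape != sigmas.shape:
        raise ValueError(
            f"activity shape {activity.shape} != sigma-field shape {sigmas.shape}"
        )
    return InhibitionOperator(sigmas, gain).apply(activity, rectify)


def feedforward(a_inh: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Fully connected linear drive: b_ij = sum_xy a_inh[x,y] * w[x,y,i,j]."""
    a_inh = np.asarray(a_inh, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[:2] != a_inh.shape:
        raise ValueError(
            f"weight tensor {weights.shape} does not match input {a_inh.shape}"
        )
    return np.tensordot(a_inh, weights, axes=2)


@dataclass(frozen=True)
class NetworkParams:
    """Model configuration (no sampled state).

    All defaults are the working parameters of the model: inhibition gain 2,
    input-layer sigma ~ N(0.67, 0.40), output-layer sigma ~ N(0.26, 0.22)
    (both truncated positive, in grid-spacing units), weights ~ N(0.5, 0.1
    variance).
    """

    input_shape: tuple = INPUT_SHAPE
    output_shape: tuple = OUTPUT_SHAPE
    gain: float = 2.0
    input_sigma_mu: float = 0.67
    input_sigma_sd: float = 0.40
    output_sigma_mu: float = 0.26
    output_sigma_sd: float = 0.22
    weight_mu: float = 0.5
    weight_var: float = 0.1
    ablate_input_li: bool = False
    ablate_output_li: bool = False
    rectify: bool = True

    def with_condition(self, condition: str) -> "NetworkParams":
        from .experiments import CONDITIONS  # local import avoids a cycle

        ablate_in, ablate_out = CONDITIONS[condition]
        return replace(self, ablate_input_li=ablate_in,
                       ablate_output_li=ablate_out)

    @classmethod
    def from_file(cls, path) -> "NetworkParams":
        """Load parameters from a YAML (or JSON) mapping of field names."""
        data = yaml.safe_load(Path(path).read_text())
        for key in ("input_shape", "output_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class Network:
    """One sampled instance of the model: weights plus both sigma fields."""

    def __init__(
        self,
        params: NetworkParams,
        weights: np.ndarray,
        input_sigmas: np.ndarray,
        output_sigmas: np.ndarray,
    ):
        self.params = params
        self.weights = weights
        self.input_sigmas = input_sigmas
        self.output_sigmas = output_sigmas
        self._input_op = None
        self._output_op = None

    @classmethod
    def sample(cls, params: NetworkParams, rng: np.random.Generator) -> "Network":
        weights = rng.normal(
            params.weight_mu,
            np.sqrt(params.weight_var),
            size=params.input_shape + params.output_shape,
        )
        input_sigmas = sample_sigma_field(
            params.input_shape, params.input_sigma_mu, params.input_sigma_sd, rng
        )
        output_sigmas = sample_sigma_field(
            params.output_shape, params.output_sigma_mu, params.output_sigma_sd, rng
        )
        return cls(params, weights, input_sigmas, output_sigmas)

    def input_response(self, image) -> np.ndarray:
        """Input-layer activity after (optional) lateral inhibition."""
        a = np.asarray(getattr(image, "intensities", image), dtype=float)
        if self.params.ablate_input_li:
            return a
        if self._input_op is None:
            self._input_op = InhibitionOperator(self.input_sigmas, self.params.gain)
        return self._input_op.apply(a, self.params.rectify)

    def respond(self, image) -> np.ndarray:
        """Full forward pass: input LI -> feedforward -> output LI."""
        b = feedforward(self.input_response(image), self.weights)
        if self.params.ablate_output_li:
            return b
        if self._output_op is None:
            self._output_op = InhibitionOperator(self.output_sigmas, self.params.gain)
        return self._output_op.apply(b, self.params.rectify)


def run_model(image, params_or_network, rng: np.random.Generator | None = None):
    """Respond to one stimulus; samples a fresh network if given bare params."""
    if isinstance(params_or_network, NetworkParams):
        if rng is None:
            raise ValueError("an rng is required to sample a network from params")
        net = Network.sample(params_or_network, rng)
    else:
        net = params_or_network
    return net.respond(image)
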