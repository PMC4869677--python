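"""Response functions and basis sets for the heart-period GLM.

A response function (RF) is the impulse response of one linear
time-invariant component of the event-related heart period response.  Each
RF is a single Gaussian parameterized by amplitude (ms), centre (seconds
relative to event onset) and width (sigma, seconds), sampled on a fixed
support of [-5, +30] s; the 5 s prestimulus interval accommodates apparent
response onsets before the stimulus that the interbeat-interval
interpolation can produce.

In the design matrix every RF enters as its *unit-peak* signed shape (the
Gaussian scaled to peak magnitude 1, keeping the sign of its amplitude), so
GLM coefficients are read directly as peak deflections in milliseconds
along the RF's direction.  The amplitude field records the component's
magnitude and direction from basis development.

A :class:`BasisSet` is an ordered (ascending centre) collection of RFs,
optionally sequentially orthogonalized with a Gram-Schmidt procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ArgumentError, DegenerateBasisError

#: RF support in seconds relative to event onset.
SUPPORT = (-5.0, 30.0)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian response component: ``a * exp(-(t-mu)^2 / (2 sigma^2))``."""

    amplitude: float  # ms, signed (negative = acceleration)
    center: float  # s relative to onset
    width: float  # sigma, s

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ArgumentError(f"width must be positive, got {self.width}")
        if not (SUPPORT[0] <= self.center <= 29.0):
            raise ArgumentError(
                f"center must lie in [{SUPPORT[0]}, 29] s, got {self.center}"
            )

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(
            -((t - self.center) ** 2) / (2.0 * self.width**2)
        )


def support_grid(fs: float) -> np.ndarray:
    """The sampling grid of the RF support at rate ``fs``."""
    return np.arange(round(SUPPORT[0] * fs), round(SUPPORT[1] * fs) + 1) / fs


@dataclass(frozen=True)
class ResponseFunction:
    """A Gaussian component together with its sampled shape."""

    component: GaussianComponent
    fs: float = 10.0
    label: str = ""

    @property
    def center(self) -> float:
        return self.component.center

    @property
    def width(self) -> float:
        return self.component.width

    @property
    def amplitude(self) -> float:
        return self.component.amplitude

    def shape(self) -> np.ndarray:
        """Full signed shape (amplitude included) on the support grid."""
        return self.component(support_grid(self.fs))

    def unit_shape(self) -> np.ndarray:
        """Signed shape normalized to unit peak magnitude."""
        shape = self.shape()
        peak = np.max(np.abs(shape))
        if peak == 0:
            raise ArgumentError(f"response function {self.label!r} is all-zero")
        return shape / peak

    @property
    def support_end(self) -> float:
        """Effective end of support, centre + 2 sigma (seconds)."""
        return self.center + 2.0 * self.width

    def overlaps(self, other: "ResponseFunction") -> bool:
        """Whether the centre +/- 2 sigma intervals of two RFs intersect."""
        lo_a, hi_a = self.center - 2 * self.width, self.center + 2 * self.width
        lo_b, hi_b = other.center - 2 * other.width, other.center + 2 * other.width
        return lo_a <= hi_b and lo_b <= hi_a


@dataclass(frozen=True)
class BasisSet:
    """Ordered RF collection; regressor shapes optionally orthogonalized.

    ``shapes`` holds one row per RF: the unit-peak signed shapes when
    ``orthogonalized`` is False, or their sequentially orthogonalized
    versions (rescaled to the input norms) when True.
    """

    rfs: tuple[ResponseFunction, ...]
    fs: float = 10.0
    orthogonalized: bool = False
    provenance: str = "custom"
    shapes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rfs = tuple(self.rfs)
        object.__setattr__(self, "rfs", rfs)
        if not rfs:
            raise ArgumentError("a basis set needs at least one response function")
        centers = [rf.center for rf in rfs]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ArgumentError("RFs must be in strictly ascending centre order")
        if any(rf.fs != self.fs for rf in rfs):
            raise ArgumentError("all RFs must share the basis sampling rate")
        if self.shapes is None:
            object.__setattr__(
                self, "shapes", np.vstack([rf.unit_shape() for rf in rfs])
            )
        else:
            shapes = np.asarray(self.shapes, dtype=float)
            if shapes.shape != (len(rfs), support_grid(self.fs).size):
                raise ArgumentError("shapes matrix does not match RF list and fs")
            object.__setattr__(self, "shapes", shapes)

    def __len__(self) -> int:
        return len(self.rfs)

    @property
    def grid(self) -> np.ndarray:
        return support_grid(self.fs)

    @property
    def max_support_end(self) -> float:
        return max(rf.support_end for rf in self.rfs)

    def truncate(self, n: int) -> "BasisSet":
        """Keep the first ``n`` RFs (validation-style reduced model).

        Orthogonalization is re-derived for the reduced set because
        sequential Gram-Schmidt of a prefix equals the prefix of the
        sequential Gram-Schmidt, so the shapes are simply the first rows.
        """
        if not 1 <= n <= len(self):
            raise ArgumentError(f"cannot truncate {len(self)} RFs to {n}")
        return BasisSet(
            self.rfs[:n],
            fs=self.fs,
            orthogonalized=self.orthogonalized,
            provenance=self.provenance,
            shapes=self.shapes[:n],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fs": self.fs,
            "orthogonalized": self.orthogonalized,
            "provenance": self.provenance,
            "rfs": [
                {
                    "amplitude_ms": rf.amplitude,
                    "center_s": rf.center,
                    "width_s": rf.width,
                    "label": rf.label,
                }
                for rf in self.rfs
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BasisSet":
        """Load a basis from JSON text or a path.

        Orthogonalized shapes are reconstructed deterministically by
        re-running Gram-Schmidt on the stored Gaussian parameters.
        """
        if isinstance(source, Path):
            text = source.read_text()
        else:
            stripped = str(source).lstrip()
            text = stripped if stripped.startswith("{") else Path(source).read_text()
        payload = json.loads(text)
        rfs = tuple(
            ResponseFunction(
                GaussianComponent(rf["amplitude_ms"], rf["center_s"], rf["width_s"]),
                fs=payload["fs"],
                label=rf.get("label", f"RF{i + 1}"),
            )
            for i, rf in enumerate(payload["rfs"])
        )
        basis = cls(rfs, fs=payload["fs"], provenance=payload.get("provenance", "custom"))
        if payload.get("orthogonalized", False):
            basis = gram_schmidt_basis(basis)
        return basis


def gram_schmidt_basis(basis: BasisSet | list[ResponseFunction]) -> BasisSet:
    """Sequentially orthogonalize RF shapes in temporal order.

    The first shape is unchanged; each later shape has its projections onto
    all earlier (already orthogonalized) shapes removed, and is rescaled to
    its input norm so amplitudes keep their millisecond interpretation.

    Raises
    ------
    DegenerateBasisError
        If a shape is (numerically) linearly dependent on its predecessors,
        i.e. its residual norm falls below 1e-12 of its input norm.
    """
    if isinstance(basis, BasisSet):
        rfs, fs, provenance = basis.rfs, basis.fs, basis.provenance
        shapes = basis.shapes.copy()
        if basis.orthogonalized:
            return basis
    else:
        rfs = tuple(sorted(basis, key=lambda rf: rf.center))
        fs = rfs[0].fs
        provenance = "custom"
        shapes = np.vstack([rf.unit_shape() for rf in rfs])

    ortho = np.empty_like(shapes)
    for k in range(shapes.shape[0]):
        v = shapes[k].copy()
        input_norm = np.linalg.norm(shapes[k])
        for j in range(k):
            v -= (ortho[j] @ shapes[k]) / (ortho[j] @ ortho[j]) * ortho[j]
        residual_norm = np.linalg.norm(v)
        if residual_norm < 1e-12 * input_norm:
            label = rfs[k].label or f"RF{k + 1}"
            raise DegenerateBasisError(
                f"{label} (centre {rfs[k].center} s) is linearly dependent on "
                "earlier response functions"
            )
        ortho[k] = v * (input_norm / residual_norm)
    return BasisSet(
        rfs, fs=fs, orthogonalized=True, provenance=provenance, shapes=ortho
    )


def canonical_basis(fs: float = 10.0) -> BasisSet:
    """The packaged six-RF model of the event-related heart period response.

    Two early components (an initial deceleration whose rise begins before
    stimulus onset, then an acceleration) are followed by four later
    components alternating in direction, covering the response out to about
    27 s post event.  Signs follow the canonical directions: decelerations
    positive, accelerations negative.
    """
    params = [
        (30.0, 1.0, 1.2),  # RF1: early deceleration (starts prestimulus)
        (-25.0, 3.5, 1.5),  # RF2: acceleration
        (-20.0, 7.0, 2.0),  # RF3
        (-15.0, 12.0, 2.5),  # RF4
        (-12.0, 17.0, 2.5),  # RF5
        (10.0, 22.0, 2.5),  # RF6: late deceleration
    ]
    rfs = tuple(
        ResponseFunction(GaussianComponent(a, c, w), fs=fs, label=f"RF{i + 1}")
        for i, (a, c, w) in enumerate(params)
    )
    return BasisSet(rfs, fs=fs, provenance="canonical")


def validation_basis(fs: float = 10.0) -> BasisSet:
    """Canonical basis with the last two RFs discarded.

    For short intertrial intervals only components peaking within the
    minimum ITI should be estimated; dropping RF5 and RF6 limits the model
    to the first ~15 s of the response.
    """
    return canonical_basis(fs).truncate(4)
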