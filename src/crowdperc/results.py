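"""Shared result containers for fitted exponents and fit metadata."""
from __future__ import annotations

import dataclasses
import json
from typing import Any


@dataclasses.dataclass
class ExponentFit:
    """A fitted quantity (phi_c, mu, alpha, z, D, ...) with its uncertainty.

    Parameters
    ----------
    name:
        Label of the fitted quantity, e.g. ``"phi_c"`` or ``"mu"``.
    value:
        Point estimate.
    stderr:
        One-sigma standard error of the estimate (``>= 0``).
    fit_window:
        ``(lo, hi)`` range of the independent variable actually used in the
        fit, with ``lo < hi``.
    metadata:
        Free-form dictionary recording fit conditions (number of points,
        held-fixed parameters, seeds, ...).
    """

    name: str
    value: float
    stderr: float
    fit_window: tuple[float, float]
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        lo, hi = self.fit_window
        if not lo < hi:
            raise ValueError("fit_window must satisfy lo < hi")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "value": float(self.value),
            "stderr": float(self.stderr),
            "fit_window": [float(self.fit_window[0]), float(self.fit_window[1])],
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExponentFit":
        return cls(
            name=d["name"],
            value=float(d["value"]),
            stderr=float(d["stderr"]),
            fit_window=(float(d["fit_window"][0]), float(d["fit_window"][1])),
            metadata=dict(d.get("metadata", {})),
        )
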