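"""Temperature-response function specifications.

Every temperature-driven process in the phenology model (development,
immature mortality, adult senescence, fecundity, oviposition timing) is
described by a small parametric function of temperature or normalized age.
A :class:`ThermalFunctionSpec` pins down which functional form is meant and
carries its named parameters, so models can be serialized to flat YAML/JSON
and round-tripped into the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FORM_PARAMS", "ThermalFunctionSpec"]

# Ordered parameter slots per functional form.  devtime_logit is variable
# arity (one intercept per rearing temperature plus a common slope) and is
# validated separately.
FORM_PARAMS: dict[str, tuple[str, ...]] = {
    "briere1": ("a", "Tmin", "Tmax"),
    "linear_rate": ("a", "b"),
    "mortality_expquad": ("b1", "b2", "b3"),
    "senescence_exponential": ("b1", "b2"),
    "senescence_stinner": ("C1", "C2", "k1", "k2", "T0"),
    "fecundity_exppoly": ("b1", "b2", "b3"),
    "fecundity_gaussian": ("y0", "a", "b", "x0"),
    "ovip_cubic_exponential": ("a", "b", "c"),
    "ovip_logistic": ("a", "b"),
    "ovip_gamma": ("a", "b"),
    "devtime_logit": (),  # 'b' plus 'intercepts'/'temperatures' lists
    "lifetable_quadratic": ("a", "b", "c"),
}


@dataclass
class ThermalFunctionSpec:
    """A functional form id plus its named parameters.

    Parameters
    ----------
    form_id:
        One of the keys of :data:`FORM_PARAMS`.
    params:
        Mapping from parameter name to value.  For ``devtime_logit`` the
        mapping holds ``b`` (common slope), ``intercepts`` (one per
        temperature) and ``temperatures``.
    param_se:
        Optional standard errors, same keys as ``params``.
    """

    form_id: str
    params: dict = field(default_factory=dict)
    param_se: dict | None = None

    def __post_init__(self) -> None:
        if self.form_id not in FORM_PARAMS:
            raise ValueError(f"unknown form_id {self.form_id!r}")
        if self.param_se is not None:
            self.param_se = {k: float(v) for k, v in self.param_se.items()}
        if self.form_id == "devtime_logit":
            self._validate_devtime()
            return
        expected = FORM_PARAMS[self.form_id]
        missing = [k for k in expected if k not in self.params]
        if missing:
            raise ValueError(f"{self.form_id}: missing parameters {missing}")
        for k in expected:
            v = float(self.params[k])
            if not math.isfinite(v):
                raise ValueError(f"{self.form_id}: parameter {k} is not finite")
            self.params[k] = v
        self._validate_constraints()

    def _validate_devtime(self) -> None:
        p = self.params
        if "b" not in p or "intercepts" not in p:
            raise ValueError("devtime_logit needs 'b' and 'intercepts'")
        b = float(p["b"])
        if not math.isfinite(b) or b <= 0:
            raise ValueError("devtime_logit: common slope b must be positive")
        p["b"] = b
        p["intercepts"] = [float(a) for a in p["intercepts"]]
        if "temperatures" in p and len(p["temperatures"]) != len(p["intercepts"]):
            raise ValueError("devtime_logit: temperatures/intercepts length mismatch")

    def _validate_constraints(self) -> None:
        p = self.params
        if self.form_id == "briere1" and not p["Tmin"] < p["Tmax"]:
            raise ValueError("briere1 requires Tmin < Tmax")
        if self.form_id == "senescence_exponential" and p["b1"] <= 0:
            raise ValueError("senescence_exponential requires b1 > 0")
        if self.form_id == "ovip_gamma" and (p["a"] <= 0 or p["b"] <= 0):
            raise ValueError("ovip_gamma requires shape a > 0 and rate b > 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"form": self.form_id, "params": dict(self.params)}
        if self.param_se is not None:
            d["param_se"] = dict(self.param_se)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalFunctionSpec":
        return cls(
            form_id=d["form"],
            params=dict(d["params"]),
            param_se=dict(d["param_se"]) if d.get("param_se") else None,
        )

    def param_vector(self) -> np.ndarray:
        """Parameters in their canonical slot order (fixed-arity forms only)."""
        return np.array([self.params[k] for k in FORM_PARAMS[self.form_id]], float)
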