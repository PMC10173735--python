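"""Parameter container for the CTL-melanoma interaction model.

All rate constants of the coupled tumor / CTL / IFNG / checkpoint ODE
system live in :class:`TumorImmuneParams`, together with box bounds used
during fitting and posterior sampling and a set of flags marking
parameters that are fixed before fitting (``kA`` and ``kex`` are not
structurally identifiable and are pinned to 1; the basal cell-cycle rates
``kgs`` and ``ksg`` are calibrated separately from untreated growth data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

#: Canonical parameter ordering used for vectorised code paths.
PARAM_ORDER = (
    "s0", "se", "dE", "di", "kgs", "ksg", "ki", "ke",
    "kA", "kex", "kl", "kt", "kp", "dl", "dt", "dp", "dpl",
)

#: Box bounds used for maximum-likelihood fitting and as flat-prior support.
#: Degradation rates are constrained to half-lives between ~10 min and 70
#: days; killing between 0.01 and 100 per CTL per day; CTL death between
#: 0.01 and 10 per day; everything else spans six orders of magnitude.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "s0": (1e-3, 1e3),
    "se": (1e-3, 1e3),
    "dE": (1e-2, 1e1),
    "di": (1e-2, 1e2),
    "kgs": (1e-3, 1e3),
    "ksg": (1e-3, 1e3),
    "ki": (1e-3, 1e3),
    "ke": (1e-2, 1e2),
    "kA": (1.0, 1.0),
    "kex": (1.0, 1.0),
    "kl": (1e-3, 1e3),
    "kt": (1e-3, 1e3),
    "kp": (1e-3, 1e3),
    "dl": (1e-2, 1e2),
    "dt": (1e-2, 1e2),
    "dp": (1e-2, 1e2),
    "dpl": (1e-2, 1e2),
}

#: Parameters pinned before fitting.  ``kA``/``kex`` are fixed to 1 (they
#: are structurally non-identifiable); ``kgs``/``ksg`` come from the
#: basal-growth calibration rather than the joint likelihood fit.
ALWAYS_FIXED = frozenset({"kA", "kex", "kgs", "ksg"})

#: Checkpoint weight active per model variant; weights not listed are
#: fixed to zero (the corresponding inhibitor is absent from exhaustion).
VARIANT_WEIGHTS: dict[str, tuple[str, ...]] = {
    "none": (),
    "lag3_only": ("kl",),
    "havcr2_only": ("kt",),
    "pdcd1_only": ("kp",),
    "all": ("kl", "kt", "kp"),
}

_CHECKPOINT_WEIGHTS = ("kl", "kt", "kp")


@dataclass(frozen=True)
class TumorImmuneParams:
    """Rate constants of the tumor-immune model.

    Units follow the day/mm^3 convention of the model: time in days after
    CTL transfer, tumor compartments in mm^3-equivalents, CTL abundance in
    per-cryosection count units, IFNG and checkpoints in arbitrary
    expression units.
    """

    s0: float = 0.0     #: CTL infiltration rate (mm^-3 day^-1)
    se: float = 0.0     #: intratumoral CTL expansion rate (day^-1)
    dE: float = 0.0     #: CTL death rate (day^-1)
    di: float = 0.0     #: IFNG disappearance rate (day^-1)
    kgs: float = 1.64   #: G1 -> S-G2-M transition rate (day^-1)
    ksg: float = 0.66   #: S-G2-M -> G1 transition rate (day^-1)
    ki: float = 0.0     #: IFNG arrest sensitivity (IFN^-1 mm^3)
    ke: float = 0.0     #: per-CTL killing rate (CTL^-1 day^-1)
    kA: float = 1.0     #: IFNG -> checkpoint induction weight (fixed 1)
    kex: float = 1.0    #: exhaustion half-effect scale (fixed 1)
    kl: float = 0.0     #: LAG3 exhaustion weight
    kt: float = 0.0     #: HAVCR2 exhaustion weight
    kp: float = 0.0     #: PDCD1*CD274 exhaustion weight
    dl: float = 1.0     #: LAG3 disappearance rate (day^-1)
    dt: float = 1.0     #: HAVCR2 disappearance rate (day^-1)
    dp: float = 1.0     #: PDCD1 disappearance rate (day^-1)
    dpl: float = 1.0    #: CD274 disappearance rate (day^-1)
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS), repr=False
    )
    fixed: frozenset[str] = field(default=ALWAYS_FIXED, repr=False)

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if self.kA != 1.0 or self.kex != 1.0:
            raise ValueError("kA and kex are fixed to 1 before fitting")
        missing = set(PARAM_ORDER) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing for parameters: {sorted(missing)}")

    # -- validation -------------------------------------------------

    def validate_bounds(self) -> None:
        """Check every free parameter lies inside its declared bounds.

        Fixed parameters (including checkpoint weights zeroed by a model
        variant) are exempt: zero lies outside the fitting box by design.
        """
        for name in PARAM_ORDER:
            if name in self.fixed:
                continue
            lo, hi = self.bounds[name]
            value = getattr(self, name)
            if value == 0.0 and name in _CHECKPOINT_WEIGHTS:
                continue  # inhibitor disabled by variant choice
            if not (lo <= value <= hi):
                raise ValueError(
                    f"parameter {name}={value} outside bounds [{lo}, {hi}]"
                )

    # -- conversions ------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Full parameter vector in :data:`PARAM_ORDER`."""
        return np.array([getattr(self, n) for n in PARAM_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec: Iterable[float], **kwargs) -> "TumorImmuneParams":
        values = dict(zip(PARAM_ORDER, np.asarray(list(vec), dtype=float)))
        return cls(**values, **kwargs)

    def with_values(self, **updates: float) -> "TumorImmuneParams":
        unknown = set(updates) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **updates)

    def free_names(self, variant: str = "all") -> tuple[str, ...]:
        """Names of parameters estimated for a given checkpoint variant.

        Checkpoint disappearance rates are always free because the
        checkpoint abundances are observed regardless of whether the
        corresponding inhibitor feeds into exhaustion.
        """
        if variant not in VARIANT_WEIGHTS:
            raise ValueError(f"unknown variant {variant!r}")
        active = VARIANT_WEIGHTS[variant]
        names = []
        for name in PARAM_ORDER:
            if name in self.fixed:
                continue
            if name in _CHECKPOINT_WEIGHTS and name not in active:
                continue
            names.append(name)
        return tuple(names)

    def apply_variant(self, variant: str) -> "TumorImmuneParams":
        """Zero the checkpoint weights excluded by ``variant``."""
        active = VARIANT_WEIGHTS[variant]  # validates variant
        updates = {w: 0.0 for w in _CHECKPOINT_WEIGHTS if w not in active}
        return self.with_values(**updates) if updates else self

    # -- serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "values": {n: getattr(self, n) for n in PARAM_ORDER},
            "bounds": {n: list(self.bounds[n]) for n in PARAM_ORDER},
            "fixed": sorted(self.fixed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TumorImmuneParams":
        return cls(
            **doc["values"],
            bounds={k: tuple(v) for k, v in doc["bounds"].items()},
            fixed=frozenset(doc.get("fixed", ALWAYS_FIXED)),
        )

    @classmethod
    def from_json(cls, path) -> "TumorImmuneParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reference_parameters(which: str = "all") -> TumorImmuneParams:
    """Best-fit reference parameter sets of the full-model analysis.

    ``"all"`` is the overall best full-model estimate (HAVCR2-dominant);
    ``"lag3_dominant"`` is the LAG3-dominant full-model local optimum.
    These serve as default ground truth for the synthetic-data generator.
    """
    common = dict(kgs=1.64, ksg=0.66, kA=1.0, kex=1.0)
    table = {
        "all": dict(s0=0.001, se=8.41, dE=0.80, di=3.61, ki=4.40, ke=100.0,
                    kl=0.001, kt=1.37, kp=0.001, dl=0.65, dt=0.01,
                    dp=2.33, dpl=2.48),
        "lag3_dominant": dict(s0=0.001, se=8.36, dE=0.80, di=3.44, ki=4.20,
                              ke=100.0, kl=1.29, kt=0.001, kp=0.001,
                              dl=0.01, dt=0.71, dp=2.08, dpl=2.29),
        "lag3_only": dict(s0=0.001, se=8.70, dE=0.77, di=3.21, ki=4.28,
                          ke=20.0, kl=1.5, kt=0.0, kp=0.0, dl=0.01,
                          dt=0.71, dp=2.27, dpl=2.32),
        "havcr2_only": dict(s0=0.001, se=8.67, dE=0.77, di=3.28, ki=4.33,
                            ke=20.0, kl=0.0, kt=1.5, kp=0.0, dl=0.64,
                            dt=0.01, dp=2.36, dpl=2.41),
    }
    if which not in table:
        raise ValueError(f"unknown reference set {which!r}")
    return TumorImmuneParams(**table[which], **common)
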