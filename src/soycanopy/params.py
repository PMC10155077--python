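"""Parameter containers and YAML config loading.

Every physiological constant used by the leaf and canopy models lives in
one flat YAML file (``data/leaf_params.yaml``) so the whole model is
re-parameterizable without touching code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

_GAS_CONSTANT = 8.314  # J mol-1 K-1
_T_REF_K = 298.15


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Leaf-level FvCB + Ball-Berry parameter set.

    Rates in umol m-2 s-1 at 25 C; ``ko25`` and ``o2`` in mmol mol-1;
    ``kc25`` and ``gamma_star25`` in umol mol-1; ``bb_intercept`` in
    mol m-2 s-1. ``ha_*`` are Arrhenius activation energies (J mol-1).
    """

    vcmax25: float = 110.0
    jmax25: float = 195.0
    rd25: float | None = None
    tpu25: float = 23.0
    theta: float = 0.7
    leaf_absorb: float = 0.85
    f_spectral: float = 0.15
    kc25: float = 405.0
    ko25: float = 278.0
    gamma_star25: float = 42.75
    o2: float = 210.0
    bb_slope: float = 9.0
    bb_intercept: float = 0.01
    ha_vcmax: float = 65330.0
    ha_jmax: float = 43540.0
    ha_rd: float = 46390.0
    ha_tpu: float = 53100.0
    ha_kc: float = 79430.0
    ha_ko: float = 36380.0
    ha_gamma_star: float = 37830.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if not 0.0 < self.leaf_absorb <= 1.0:
            raise ValueError("leaf_absorb must be in (0, 1]")
        if self.gamma_star25 >= self.kc25:
            raise ValueError("gamma_star25 must be below kc25")
        for name in ("vcmax25", "jmax25", "tpu25", "kc25", "ko25",
                     "gamma_star25", "o2", "bb_slope", "bb_intercept"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def rd25_effective(self) -> float:
        """Dark respiration at 25 C; defaults to 1.5% of vcmax25."""
        return self.rd25 if self.rd25 is not None else 0.015 * self.vcmax25

    @property
    def absorb_effective(self) -> float:
        """Fraction of incident PPFD delivered to photosystem II."""
        return self.leaf_absorb * (1.0 - self.f_spectral) / 2.0

    def scaled(self, scale_v: float = 1.0, scale_j: float = 1.0) -> "PhotosynthesisParams":
        """Scale vcmax25 (and, with it, rd25 and tpu25) and jmax25.

        Respiration and TPU capacity track the carboxylation scaling so a
        V+20%/J+20% experiment also pays the respiration penalty and keeps
        TPU rarely limiting across the whole scaling grid.
        """
        return replace(
            self,
            vcmax25=self.vcmax25 * scale_v,
            jmax25=self.jmax25 * scale_j,
            rd25=self.rd25_effective * scale_v,
            tpu25=self.tpu25 * scale_v,
        )

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "PhotosynthesisParams":
        """Load parameters from a flat YAML file (package default if None)."""
        if path is None:
            ref = importlib.resources.files("soycanopy.data") / "leaf_params.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown leaf parameter keys: {sorted(unknown)}")
        return cls(**raw)


def arrhenius(value25: float, ha: float, t_leaf_c: float):
    """Arrhenius temperature scaling relative to 25 C.

    Returns ``value25 * exp(ha/R * (1/298.15 - 1/T))``; exact identity at
    25 C. Accepts scalars or numpy arrays for ``t_leaf_c``.
    """
    import numpy as np

    t_k = np.asarray(t_leaf_c, dtype=float) + 273.15
    out = value25 * np.exp(ha / _GAS_CONSTANT * (1.0 / _T_REF_K - 1.0 / t_k))
    if np.ndim(t_leaf_c) == 0:
        return float(out)
    return out


def load_crop_config(path: str | Path | None = None) -> dict:
    """Load the soybean growth/canopy config as a plain dict."""
    if path is None:
        ref = importlib.resources.files("soycanopy.data") / "crop_soybean.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())
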