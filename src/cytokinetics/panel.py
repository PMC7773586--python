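"""Ground-truth kinetic templates for the cytokinesis protein panel.

Each protein's accumulation at the bud neck is modelled as a baseline plus a
sum of asymmetric Gaussian bumps: every bump has a peak time ``mu`` (minutes
relative to spindle breakage), an amplitude (a.u.), and separate rise/fall
widths so that proteins with attenuated recruitment (e.g. Cyk3) or slow
removal (e.g. Fks1) keep their published shapes.  The packaged panel encodes
the published peak/arrival/departure times for 25 budding-yeast cytokinesis
proteins across six functional modules; values without a published anchor are
marked ``decision`` in the provenance block of the YAML file.

Perturbations (latrunculin-A treatment, gene deletions) are expressed as
:class:`ConditionEffect` objects acting on a template in *measurement space*:
the amplitude factor is the ratio of raw peak values, the rate factor is the
ratio of maximal 5-min rising slopes, and the peak shift is additive in
minutes.  ``apply_condition`` inverts this measurement model so that the
modified template reproduces the configured factors when re-measured.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

DEFAULT_GRID = np.arange(-45.0, 46.0)  # minutes relative to spindle breakage

__all__ = [
    "Bump",
    "TemplateCurve",
    "ConditionEffect",
    "PanelError",
    "load_signature_table",
    "load_conditions",
    "apply_condition",
    "DEFAULT_GRID",
]


class PanelError(ValueError):
    """Raised when a packaged or user panel file fails validation."""


class Bump(BaseModel):
    """One asymmetric Gaussian component of a template curve."""

    mu: float
    amplitude: float = Field(gt=0.0)
    rise: float = Field(gt=0.0, description="rise width sigma_L, min")
    fall: float = Field(gt=0.0, description="fall width sigma_R, min")


class TemplateCurve(BaseModel):
    """Noise-free accumulation curve of one protein at the division site."""

    protein_id: str
    module: str = "unassigned"
    baseline: float = Field(ge=0.0)
    bumps: list[Bump]
    arrival_time: float
    departure_time: float
    fall_mode: str = "gaussian"  # "linear" models disassembly without constriction
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_ordering(self) -> "TemplateCurve":
        if not self.bumps:
            raise ValueError(f"{self.protein_id}: template needs at least one bump")
        mus = [b.mu for b in self.bumps]
        if not self.arrival_time < min(mus):
            raise ValueError(f"{self.protein_id}: arrival must precede first peak")
        if not self.departure_time > max(mus):
            raise ValueError(f"{self.protein_id}: departure must follow last peak")
        if self.fall_mode not in ("gaussian", "linear"):
            raise ValueError(f"{self.protein_id}: unknown fall_mode {self.fall_mode!r}")
        return self

    # -- evaluation ---------------------------------------------------------

    @property
    def primary_peak_time(self) -> float:
        """Time of the highest bump (evaluation of the full curve at bump mus)."""
        mus = np.array([b.mu for b in self.bumps])
        vals = self._eval_gaussian(mus)
        return float(mus[int(np.argmax(vals))])

    def peak_value(self) -> float:
        """Raw curve value at the primary peak (baseline included)."""
        return float(self._eval_gaussian(np.array([self.primary_peak_time]))[0])

    def _eval_gaussian(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline, dtype=float)
        for b in self.bumps:
            sigma = np.where(t < b.mu, b.rise, b.fall)
            out += b.amplitude * np.exp(-0.5 * ((t - b.mu) / sigma) ** 2)
        return out

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template; always >= baseline."""
        t = np.asarray(t, dtype=float)
        out = self._eval_gaussian(t)
        if self.fall_mode == "linear":
            # disassembly without constriction: linear decline from the primary
            # peak back to baseline at departure_time
            tp = self.primary_peak_time
            vp = self.peak_value()
            span = self.departure_time - tp
            frac = np.clip((t - tp) / span, 0.0, 1.0)
            linear = vp + (self.baseline - vp) * frac
            out = np.where(t > tp, linear, out)
        return np.maximum(out, self.baseline)


class ConditionEffect(BaseModel):
    """Perturbation of one protein's kinetics, in measurement space."""

    amplitude_factor: float = Field(default=1.0, ge=0.0)
    peak_shift: float = 0.0
    rate_factor: Optional[float] = Field(default=None, gt=0.0)
    constrict: bool = True
    fall_mode: Optional[str] = None
    fast_rate_factor: float = Field(default=1.0, gt=0.0)


# -- measurement helpers shared with the kinetics stage ----------------------


def max_rising_slope(times: np.ndarray, values: np.ndarray, window: float = 5.0) -> float:
    """Maximal slope of a sliding-window linear fit before the curve peak.

    This is the operational definition of an accumulation *rate*: the largest
    slope of any ``window``-minute least-squares line fitted to the curve at
    times up to and including its global maximum.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ipk = int(np.argmax(values))
    best = -np.inf
    for i in range(ipk + 1):
        sel = (times >= times[i]) & (times <= times[i] + window) & (times <= times[ipk])
        if sel.sum() < 3:
            continue
        slope = np.polyfit(times[sel], values[sel], 1)[0]
        best = max(best, float(slope))
    if not np.isfinite(best):
        raise ValueError("curve too short to measure a rising slope")
    return best


def apply_condition(template: TemplateCurve, effect: ConditionEffect,
                    grid: np.ndarray | None = None) -> TemplateCurve:
    """Return a new template whose measured kinetics reproduce ``effect``.

    The peak shift is additive on all bump times; the amplitude factor is
    enforced on the raw peak value (baseline included); the rate factor, when
    given, is enforced on the max 5-min rising slope by stretching the rise
    widths (solved numerically against the unperturbed template on ``grid``).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    bumps = [b.model_copy() for b in template.bumps]
    for b in bumps:
        b.mu += effect.peak_shift
    arrival = template.arrival_time + effect.peak_shift
    departure = template.departure_time + effect.peak_shift

    # amplitude: scale bump heights so that raw peak value ratio == factor
    v_ctrl = template.peak_value()
    target_peak = effect.amplitude_factor * v_ctrl
    g = (target_peak - template.baseline) / (v_ctrl - template.baseline)
    g = max(g, 1e-6)
    for b in bumps:
        b.amplitude *= g

    fall_mode = effect.fall_mode or template.fall_mode
    out = TemplateCurve(
        protein_id=template.protein_id,
        module=template.module,
        baseline=template.baseline,
        bumps=bumps,
        arrival_time=min(arrival, min(b.mu for b in bumps) - 1e-6),
        departure_time=max(departure, max(b.mu for b in bumps) + 1e-6),
        fall_mode=fall_mode,
        provenance=dict(template.provenance),
    )

    if effect.rate_factor is not None:
        rate_ctrl = max_rising_slope(grid, template(grid))
        target = effect.rate_factor * rate_ctrl

        def _with_stretch(s: float) -> TemplateCurve:
            stretched = [
                Bump(mu=b.mu, amplitude=b.amplitude, rise=b.rise * s, fall=b.fall)
                for b in out.bumps
            ]
            return out.model_copy(update={
                "bumps": stretched,
                "arrival_time": min(out.arrival_time,
                                    min(b.mu for b in stretched) - 1e-6),
            })

        def _objective(s: float) -> float:
            return max_rising_slope(grid, _with_stretch(s)(grid)) - target

        lo, hi = 1.0, 1.0
        while _objective(hi) > 0 and hi < 512:
            hi *= 2.0
        if _objective(hi) > 0:
            raise PanelError(
                f"{template.protein_id}: rate_factor {effect.rate_factor} not "
                "reachable by rise stretching")
        if hi > 1.0:
            s = brentq(_objective, lo, hi, xtol=1e-4)
            out = _with_stretch(s)
    return out


# -- packaged panel -----------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cytokinetics") / "data" / name))


def load_signature_table(config_path: str | Path | None = None) -> list[TemplateCurve]:
    """Load the protein panel from YAML (the packaged table by default)."""
    path = Path(config_path) if config_path is not None else _data_path("panel.yaml")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - depends on file content
        raise PanelError(f"malformed panel file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "proteins" not in raw:
        raise PanelError(f"panel file {path} has no 'proteins' section")
    panel: list[TemplateCurve] = []
    for entry in raw["proteins"]:
        name = entry.get("id", "<unnamed>") if isinstance(entry, dict) else "<unnamed>"
        try:
            panel.append(TemplateCurve(
                protein_id=entry["id"],
                module=entry.get("module", "unassigned"),
                baseline=float(entry["baseline"]),
                bumps=[Bump(**b) for b in entry["bumps"]],
                arrival_time=float(entry["arrival"]),
                departure_time=float(entry["departure"]),
                provenance=entry.get("provenance", {}),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise PanelError(f"malformed panel entry {name!r}: {exc}") from exc
    return panel


def load_conditions(config_path: str | Path | None = None) -> dict[str, dict[str, ConditionEffect]]:
    """Load condition definitions: mapping condition -> protein -> effect.

    Global keys of a condition (``constrict``, ``fall_mode``,
    ``fast_rate_factor``) are merged into every per-protein effect.
    """
    path = Path(config_path) if config_path is not None else _data_path("conditions.yaml")
    raw = yaml.safe_load(path.read_text()) or {}
    out: dict[str, dict[str, ConditionEffect]] = {}
    for cond, block in raw.items():
        block = block or {}
        base = {k: block[k] for k in ("constrict", "fall_mode", "fast_rate_factor")
                if k in block}
        effects = {}
        for prot, spec_ in (block.get("effects") or {}).items():
            effects[prot] = ConditionEffect(**{**base, **(spec_ or {})})
        effects["__default__"] = ConditionEffect(**base)
        out[cond] = effects
    return out


def panel_by_id(panel: Sequence[TemplateCurve]) -> dict[str, TemplateCurve]:
    return {t.protein_id: t for t in panel}
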