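"""Scalar biomarkers of a paced action potential.

The repolarization biomarkers APDp (p = 20 ... 90) are measured
threshold-to-threshold: the level ``v_p = v_max - (p/100) * (v_max - v_min)``
is crossed once on the upstroke and once during repolarization, both
crossing times found by linear interpolation between samples, and APDp is
their difference.  ``v_min`` is the pre-stimulus diastolic minimum (samples
before the maximal-upstroke time), so a stimulus artifact cannot redefine
the baseline; ``v_max`` is the global maximum.  The maximal upstroke
velocity dv/dt_max is the largest forward-difference slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apmodel import PacedTrace

__all__ = ["APD_LEVELS", "BiomarkerSet", "compute_biomarkers", "percent_change"]

APD_LEVELS = (20, 30, 40, 50, 60, 70, 80, 90)

#: minimal AP amplitude (mV) below which a trace is "no action potential"
MIN_AMPLITUDE = 10.0


@dataclass
class BiomarkerSet:
    """APD map (ms), extreme voltages (mV) and optional upstroke velocity."""

    apd: dict[int, float]
    v_max: float
    v_min: float
    dvdt_max: float | None = None

    def as_dict(self) -> dict:
        out = {
            "apd": {str(p): float(self.apd[p]) for p in sorted(self.apd)},
            "v_max": float(self.v_max),
            "v_min": float(self.v_min),
        }
        if self.dvdt_max is not None:
            out["dvdt_max"] = float(self.dvdt_max)
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "BiomarkerSet":
        return cls(
            apd={int(p): float(x) for p, x in doc["apd"].items()},
            v_max=float(doc["v_max"]),
            v_min=float(doc["v_min"]),
            dvdt_max=float(doc["dvdt_max"]) if "dvdt_max" in doc else None,
        )

    def value(self, key: str) -> float:
        """Look up a biomarker by string key ('apd50', 'v_max', ...)."""
        if key.startswith("apd"):
            return self.apd[int(key[3:])]
        val = getattr(self, key)
        if val is None:
            raise KeyError(f"biomarker {key!r} not present")
        return val


def _cross_time(t0, v0, t1, v1, level):
    # linear interpolation of the crossing of `level` between two samples
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def compute_biomarkers(trace: PacedTrace, include_dvdt: bool = False) -> BiomarkerSet:
    """Extract the biomarker set from a single-beat trace.

    Raises ValueError("no action potential detected") when the amplitude is
    below 10 mV and ValueError("incomplete repolarization") when the trace
    never returns below the 90%-repolarization level after the peak.
    """
    t = np.asarray(trace.time, dtype=float)
    v = np.asarray(trace.voltage, dtype=float)
    if t.size < 3:
        raise ValueError("no action potential detected (trace too short)")

    dvdt = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[i_up])

    i_peak = int(np.argmax(v))
    v_max = float(v[i_peak])
    # diastolic minimum: before the fastest upstroke (fall back to global)
    v_min = float(np.min(v[: i_up + 1])) if i_up > 0 else float(np.min(v))

    if v_max - v_min < MIN_AMPLITUDE:
        raise ValueError("no action potential detected")

    apd = {}
    for p in APD_LEVELS:
        level = v_max - (p / 100.0) * (v_max - v_min)
        # upstroke crossing: first upward crossing at or before the peak
        pre = np.nonzero((v[:i_peak] < level) & (v[1 : i_peak + 1] >= level))[0]
        if pre.size == 0:
            raise ValueError("no action potential detected (no upstroke crossing)")
        k = int(pre[0])
        up = _cross_time(t[k], v[k], t[k + 1], v[k + 1], level)
        # repolarizing crossing: first downward crossing after the peak
        post = np.nonzero(
            (v[i_peak:-1] >= level) & (v[i_peak + 1 :] < level)
        )[0]
        if post.size == 0:
            raise ValueError("incomplete repolarization")
        k = int(post[0]) + i_peak
        down = _cross_time(t[k], v[k], t[k + 1], v[k + 1], level)
        apd[p] = float(down - up)

    return BiomarkerSet(
        apd=apd,
        v_max=v_max,
        v_min=v_min,
        dvdt_max=dvdt_max if include_dvdt else None,
    )


def percent_change(control: float, treated: float) -> float:
    """Signed percent change 100 * (treated - control) / control."""
    if control == 0:
        raise ValueError("percent change undefined for control value 0")
    return 100.0 * (treated - control) / control
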