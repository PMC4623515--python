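"""Hormonal regulation of transporter activities.

Transporter activity levels E are dimensionless fractions in [0, 1], computed
per cell from the cell-average hormone concentrations through sigmoidal Hill
response curves.  The activity is a quasi-steady algebraic function of the
current averages: E stands for the net outcome of transcription, translation
and trafficking, with no explicit delay.

Regulation modes:

* ``static`` — the carrier is always fully active (E = 1).
* ``auxin-up`` — activity rises with cell auxin (PIN3; the importer during
  lateral-root initiation).
* ``ck-up-auxin-down`` — activity rises with cytokinin and is simultaneously
  repressed by auxin (PIN1 and PIN7; the auxin arm abstracts the
  auxin → AHP6 → cytokinin-response inhibition into a direct down-regulation).

Auxin-driven cytokinin biosynthesis replaces the uniform cytokinin synthesis
rate by a Hill function of cell auxin scaled by K_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "REGULATION_MODES",
    "RegulationParams",
    "hill_up",
    "hill_down",
    "transporter_activity",
    "cytokinin_synthesis_rate",
]

REGULATION_MODES = ("static", "auxin-up", "ck-up-auxin-down")


@dataclass(frozen=True)
class RegulationParams:
    """Half-maximum constants and Hill coefficients (concentrations in a.u.).

    ``K_A_cyt`` is the cytokinin level at which PIN up-regulation is
    half-maximal (10 for the no-gradient baseline, 0.6 in steep-gradient
    runs); ``K_A_PIN`` / ``K_A_AUX`` are the auxin half-maxima for PIN and
    importer regulation; ``n`` is the shared Hill coefficient.  The
    cytokinin-biosynthesis feedback uses ``K_A_auxin``, ``K_s`` and ``m``.
    """

    K_A_cyt: float = 10.0
    K_A_PIN: float = 100.0
    K_A_AUX: float = 100.0
    n: float = 2.0
    K_A_auxin: float = 0.01
    K_s: float = 6.0
    m: float = 5.0

    def __post_init__(self) -> None:
        for name in ("K_A_cyt", "K_A_PIN", "K_A_AUX", "K_A_auxin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n < 1 or self.m < 1:
            raise ValueError("Hill coefficients must be >= 1")


def _check_nonneg(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hormone concentration must be non-negative")
    return x


def hill_up(x, K: float, n: float):
    """Activating Hill response (x/K)^n / ((x/K)^n + 1).

    Strictly increasing in x, 0 at x = 0, 1/2 at x = K, -> 1 as x -> inf.
    """
    x = _check_nonneg(x)
    if K <= 0:
        raise ValueError("K must be positive")
    u = (x / K) ** n
    out = u / (u + 1.0)
    return float(out) if out.ndim == 0 else out


def hill_down(x, K: float, n: float):
    """Inhibitory Hill response 1 / ((x/K)^n + 1); hill_up + hill_down = 1."""
    x = _check_nonneg(x)
    if K <= 0:
        raise ValueError("K must be positive")
    u = (x / K) ** n
    out = 1.0 / (u + 1.0)
    return float(out) if out.ndim == 0 else out


def activity_from_mode(mode: str, auxin, cytokinin, params: RegulationParams):
    """Activity E in [0, 1] for a regulation mode, vectorized over cells."""
    if mode == "static":
        return np.ones_like(np.asarray(auxin, dtype=float))
    if mode == "auxin-up":
        # PIN3 and AUX1 share the auxin half-maximum value (Table-level equality)
        return hill_up(auxin, params.K_A_AUX, params.n)
    if mode == "ck-up-auxin-down":
        return hill_up(cytokinin, params.K_A_cyt, params.n) * hill_down(
            auxin, params.K_A_PIN, params.n
        )
    raise ValueError(f"unknown regulation mode {mode!r}")


#: default regulation mode of each transporter kind
DEFAULT_MODES = {
    "PIN1": "ck-up-auxin-down",
    "PIN3": "auxin-up",
    "PIN7": "ck-up-auxin-down",
    "PIN7weak": "ck-up-auxin-down",
    "exporter_outer": "static",
    "importer": "static",
}


def transporter_activity(
    kind: str,
    cell_auxin,
    cell_cytokinin,
    params: RegulationParams | None = None,
    static: bool = False,
    mode: str | None = None,
):
    """Relative activity E of one transporter kind from cell hormone averages.

    ``static=True`` reproduces the unregulated ('static') simulations in which
    every carrier is constantly expressed at full strength.  ``mode``
    overrides the kind's default regulation (e.g. the importer switching to
    auxin-up in pericycle cells during lateral-root initiation).
    """
    params = params or RegulationParams()
    if kind not in DEFAULT_MODES:
        raise ValueError(f"unknown transporter kind {kind!r}")
    if static:
        return activity_from_mode("static", cell_auxin, cell_cytokinin, params)
    use = mode if mode is not None else DEFAULT_MODES[kind]
    if use == "auxin-up" and kind.startswith("PIN"):
        x = _check_nonneg(cell_auxin)
        out = hill_up(x, params.K_A_PIN, params.n)
        return out
    return activity_from_mode(use, cell_auxin, cell_cytokinin, params)


def cytokinin_synthesis_rate(cell_auxin, params: RegulationParams, b_cyt: float):
    """Auxin-driven cytokinin biosynthesis rate (a.u. s^-1 um^-2).

    K_s * auxin^m / (K_A_auxin^m + auxin^m) * b_cyt; bounded by K_s * b_cyt.
    """
    x = _check_nonneg(cell_auxin)
    out = params.K_s * hill_up(x, params.K_A_auxin, params.m) * b_cyt
    return float(out) if np.ndim(out) == 0 else out
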