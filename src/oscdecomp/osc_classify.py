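"""Classification of extracted oscillators into physiological classes.

Fitted oscillators of a bivariate (oxy, deoxy) channel are labeled by
frequency band and oxy-to-deoxy phase delay:

* ``brain`` -- 0.01-0.1 Hz slow hemodynamic oscillations;
* ``pulse`` -- cardiac-band (1.6-2.4 Hz) oscillators superposed on oxy and
  deoxy nearly in phase (blood-volume pulsation);
* ``mirror`` -- cardiac-band oscillators in anti-phase, the signature of
  measurement noise pushed through the two-wavelength Lambert-Beer
  inversion;
* ``harmonic`` -- 3.6-4.4 Hz components, the second harmonic of the pulse;
* ``other`` -- anything else.

The in-phase/anti-phase split uses a 90-degree circular half-width (the
midpoint between the two observed phase peaks at 0 and 180 degrees).
Projection norms are reported but deliberately not used as classification
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .osc_fit import DecompResult

__all__ = ["ClassificationBands", "OscillatorLabel", "classify_oscillators", "circular_distance_deg"]


def circular_distance_deg(x: float, y: float) -> float:
    """Shortest angular distance between two angles in degrees, in [0, 180]."""
    d = abs(x - y) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class ClassificationBands:
    """Frequency-band edges (Hz) and the in-phase/anti-phase half-width (deg)."""

    brain: tuple = (0.01, 0.1)
    cardiac: tuple = (1.6, 2.4)
    harmonic: tuple = (3.6, 4.4)
    inphase_halfwidth_deg: float = 90.0


@dataclass(frozen=True)
class OscillatorLabel:
    """One fitted oscillator with its class label and summary parameters."""

    kind: str
    oscillator: int
    frequency: float
    phase_diff_deg: float
    deoxy_norm: float
    power: float
    regularity: float


def classify_oscillators(decomp, bands: ClassificationBands | None = None) -> list:
    """Label every oscillator of a bivariate decomposition.

    ``decomp`` is a DecompResult (or a bare OscModel) from a J = 2 fit with
    series order (oxy, deoxy).  Classification depends only on frequency and
    phase delay; every oscillator receives a label.
    """
    bands = bands or ClassificationBands()
    model = decomp.best.model if isinstance(decomp, DecompResult) else decomp
    if model.J < 2:
        raise ValueError("classification requires a bivariate (oxy, deoxy) fit")
    labels = []
    for k, osc in enumerate(model.oscillators):
        phase = model.phase_delay_deg(1, k)
        if bands.brain[0] <= osc.f <= bands.brain[1]:
            kind = "brain"
        elif bands.cardiac[0] <= osc.f <= bands.cardiac[1]:
            if circular_distance_deg(phase, 0.0) < bands.inphase_halfwidth_deg:
                kind = "pulse"
            else:
                kind = "mirror"
        elif bands.harmonic[0] <= osc.f <= bands.harmonic[1]:
            kind = "harmonic"
        else:
            kind = "other"
        labels.append(
            OscillatorLabel(
                kind=kind,
                oscillator=k,
                frequency=osc.f,
                phase_diff_deg=phase,
                deoxy_norm=model.projection_norm(1, k),
                power=osc.power,
                regularity=osc.a,
            )
        )
    return labels
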