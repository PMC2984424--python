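"""Synthetic nuclei point patterns with mitotic labels.

Stand-in for mitosis-marker (α-PH3-style) labelled embryo preparations: nuclei
are scattered uniformly over a unit rectangle whose first axis is the
anterior–posterior (AP) body axis, and each nucleus is independently mitotic
with a position-dependent probability.  Three labelling regimes are generated:

``uniform``
    Constant mitotic probability ``p0`` everywhere — dividing cells scattered
    over the whole germ band with no posterior hotspot.
``posterior_zone``
    Probability elevated by factor ``enrichment`` in the posterior-most
    fraction ``zone_fraction`` of the AP axis — a localized terminal
    proliferation zone (the positive-control regime).
``ring``
    Probability elevated by ``enrichment`` inside an annulus — a concentric
    ring of proliferating cells such as those seen around a forming appendage.

The geometry is deliberately a flat 2D rectangle: the downstream zone test
consumes only the AP coordinate, so curvature of a real embryo is cosmetic
here.  All randomness goes through one seeded numpy Generator; a fixed
(scenario, params, seed) triple reproduces the pattern bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointPattern", "SCENARIOS", "generate"]

SCENARIOS = ("uniform", "posterior_zone", "ring")


@dataclass
class PointPattern:
    """Nuclei with mitotic labels on the unit rectangle.

    ``ap`` runs 0 (anterior) to 1 (posterior); ``lat`` is the lateral
    coordinate; ``mitotic`` marks labelled nuclei.  ``params`` echoes the
    scenario parameters used to generate the pattern.
    """

    ap: np.ndarray
    lat: np.ndarray
    mitotic: np.ndarray
    scenario: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_nuclei(self) -> int:
        return self.ap.size

    @property
    def n_mitotic(self) -> int:
        return int(self.mitotic.sum())


def generate(
    scenario: str,
    n_nuclei: int = 2000,
    *,
    p0: float = 0.05,
    enrichment: float = 10.0,
    zone_fraction: float = 0.1,
    ring_center: tuple[float, float] = (0.5, 0.5),
    ring_radius: float = 0.25,
    ring_width: float = 0.1,
    seed: int | None = None,
) -> PointPattern:
    """Draw a labelled nuclei pattern for one scenario.

    Positions are uniform on the unit rectangle; labels are Bernoulli with
    probability ``p0`` at baseline, raised to ``p0 * enrichment`` inside the
    scenario's hotspot (posterior strip ``ap > 1 - zone_fraction``, or the
    annulus ``|dist(center) - ring_radius| <= ring_width / 2``).

    Raises ``ValueError`` for probabilities outside (0, 1), including
    ``p0 * enrichment >= 1``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be positive")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if not 0 < zone_fraction < 1:
        raise ValueError("zone_fraction must lie in (0, 1)")
    if scenario != "uniform" and p0 * enrichment >= 1:
        raise ValueError("p0 * enrichment must be < 1")

    rng = np.random.default_rng(seed)
    ap = rng.uniform(0.0, 1.0, n_nuclei)
    lat = rng.uniform(0.0, 1.0, n_nuclei)

    p = np.full(n_nuclei, p0)
    params: dict = {"p0": p0}
    if scenario == "posterior_zone":
        p[ap > 1.0 - zone_fraction] = p0 * enrichment
        params.update(enrichment=enrichment, zone_fraction=zone_fraction)
    elif scenario == "ring":
        r = np.hypot(ap - ring_center[0], lat - ring_center[1])
        p[np.abs(r - ring_radius) <= 0.5 * ring_width] = p0 * enrichment
        params.update(
            enrichment=enrichment,
            ring_center=ring_center,
            ring_radius=ring_radius,
            ring_width=ring_width,
        )
    mitotic = rng.uniform(0.0, 1.0, n_nuclei) < p

    return PointPattern(
        ap=ap, lat=lat, mitotic=mitotic, scenario=scenario, params=params, seed=seed
    )
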