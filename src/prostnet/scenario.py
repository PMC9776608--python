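"""The three-phase in-silico treatment experiment.

Starting from the unperturbed network at its steady state, three drug
interventions are applied in sequence, each halving one base-production
term:

* t = 50 — androgen ablation (J_AR: 1.5 → 0.75), modelling castration or
  AR-antagonist therapy;
* t = 100 — NF-κB inhibition (J_p65: 2 → 1), modelling anti-inflammatory
  treatment;
* t = 150 — PI3K inhibition (J_PI3K: 2 → 1).

The biological predictions under test are directional: NF-κB *and* c-Myc
activity rise after androgen ablation; inhibiting NF-κB then brings c-Myc
slightly below its pre-ablation level; inhibiting PI3K depresses c-Myc and
NF-κB further still.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ar_nfkb_model
from .simulate import (
    PerturbationEvent,
    SimulationConfig,
    Trajectory,
    phase_summary,
    simulate,
)

__all__ = ["ScenarioReport", "ablation_scenario", "direction_check", "CLAIMS"]

X0 = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
EVENT_TIMES = (50.0, 100.0, 150.0)
EVENT_NODES = ("AR", "p65", "PI3K")
# late window = final 40% of each regime, excluding the post-switch transient
LATE_FRACTION = 0.4

#: Named directional claims evaluated by :func:`direction_check`.
CLAIMS = (
    "p65_up_after_ar_ablation",
    "cmyc_up_after_ar_ablation",
    "cmyc_below_baseline_after_nfkb_inhibition",
    "cmyc_further_down_after_pi3k_inhibition",
    "p65_further_down_after_pi3k_inhibition",
)


@dataclass(frozen=True)
class ScenarioReport:
    """Simulation output and windowed summaries of the treatment scenario.

    ``baseline`` is the per-node mean over the late pre-treatment window;
    ``regime_means[r]`` the per-node mean over the late window of regime
    ``r`` (0 = after AR ablation, 1 = after NF-κB inhibition, 2 = after
    PI3K inhibition).  ``directions[r][node]`` classifies each node's
    change across the r-th transition as "up", "down" or "flat" at the
    relative tolerance used to build the report.
    """

    trajectory: Trajectory
    labels: tuple[str, ...]
    baseline: np.ndarray
    regime_means: np.ndarray
    regime_windows: tuple[tuple[float, float], ...]
    directions: tuple[dict[str, str], ...]
    tolerance: float

    def mean(self, regime: int, node: str) -> float:
        """Late-window mean of one node; regime -1 is the baseline."""
        i = self.labels.index(node)
        return float(self.baseline[i] if regime < 0 else self.regime_means[regime, i])


def _classify(new: float, ref: float, tol: float) -> str:
    scale = abs(ref) if ref != 0 else 1.0
    if new - ref > tol * scale:
        return "up"
    if ref - new > tol * scale:
        return "down"
    return "flat"


def ablation_scenario(
    seed: int | None = None,
    t_end: float = 200.0,
    noise_amplitude: float = 0.0,
    dt: float = 0.001,
    tolerance: float = 0.01,
) -> ScenarioReport:
    """Run the AR-ablation / NF-κB-inhibition / PI3K-inhibition experiment.

    Integrates the default six-node model from t = 0 with the three
    scheduled factor-1/2 switches and summarises each regime over the
    final 40% of its span.  ``t_end`` must exceed the last switch at
    t = 150.  Noise is off by default; with ``noise_amplitude`` > 0 the
    run is reproducible under ``seed``.
    """
    if t_end <= EVENT_TIMES[-1]:
        raise ValueError(f"t_end must exceed {EVENT_TIMES[-1]}")
    model = ar_nfkb_model()
    config = SimulationConfig(
        x0=np.array(X0),
        dt=dt,
        t_start=0.0,
        t_end=t_end,
        noise_amplitude=noise_amplitude,
        seed=seed,
    )
    schedule = [
        PerturbationEvent(time=t, node=node, factor=0.5)
        for t, node in zip(EVENT_TIMES, EVENT_NODES)
    ]
    traj = simulate(model, config, schedule)

    bounds = (0.0, *EVENT_TIMES, t_end)
    windows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        span = hi - lo
        windows.append((hi - LATE_FRACTION * span, hi))
    means = phase_summary(traj, windows)
    baseline, regime_means = means[0], means[1:]

    refs = [baseline] + [regime_means[r] for r in range(len(regime_means) - 1)]
    directions = tuple(
        {
            label: _classify(regime_means[r, i], refs[r][i], tolerance)
            for i, label in enumerate(model.labels)
        }
        for r in range(len(regime_means))
    )
    return ScenarioReport(
        trajectory=traj,
        labels=model.labels,
        baseline=baseline,
        regime_means=regime_means,
        regime_windows=tuple(windows[1:]),
        directions=directions,
        tolerance=tolerance,
    )


def direction_check(
    report: ScenarioReport, tolerance: float = 0.01
) -> dict[str, bool]:
    """Evaluate the named directional treatment-response claims.

    Each claim compares two late-window means with relative tolerance
    ``tolerance``: a rise/fall smaller than ``tolerance · |reference|``
    counts as flat and fails.  Returns ``{claim: passed}`` for the claims
    in :data:`CLAIMS`.
    """
    if report.regime_means.shape[0] != 3:
        raise ValueError("report must contain the three treatment regimes")

    def up(new: float, ref: float) -> bool:
        return _classify(new, ref, tolerance) == "up"

    def down(new: float, ref: float) -> bool:
        return _classify(new, ref, tolerance) == "down"

    m = report.mean
    return {
        "p65_up_after_ar_ablation": up(m(0, "p65"), m(-1, "p65")),
        "cmyc_up_after_ar_ablation": up(m(0, "cMyc"), m(-1, "cMyc")),
        "cmyc_below_baseline_after_nfkb_inhibition": down(m(1, "cMyc"), m(-1, "cMyc")),
        "cmyc_further_down_after_pi3k_inhibition": down(m(2, "cMyc"), m(1, "cMyc")),
        "p65_further_down_after_pi3k_inhibition": down(m(2, "p65"), m(1, "p65")),
    }
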