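"""Consciousness-detection decision rule over three classification metrics.

* m1 — can stimulus classes be told apart in the **active** mode
  (standard vs deviant; correct vs incorrect novel)?
* m2 — can the **active** and **breathing** modes be told apart under each
  stimulus type?
* m3 — does averaging test trials (1 → 5) raise the accuracy, as it should
  when a genuine phase-locked signal is buried in noise?

"Above chance" is formalized as exceeding the one-sided exact binomial
95th-percentile accuracy under p = 0.5 for the test-set size at hand.
The verdict ladder is:

* no m1 accuracy above chance, even after trial averaging → ``no_evidence``;
* m1 above chance but neither m2 above chance nor a positive m3 gain
  (> 2·SE of the single-trial accuracy) → ``potentially_conscious``;
* m1 above chance and either m2 above chance or a positive m3 gain →
  ``consciousness_detected``.

The numeric thresholds of this ladder are this package's formalization of
a procedure published only as a flowchart; reports carry a note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

VERDICTS = ("no_evidence", "potentially_conscious", "consciousness_detected")

FORMALIZATION_NOTE = (
    "Chance level is the one-sided exact binomial bound at alpha; the "
    "branching thresholds are this package's formalization of the "
    "published decision flowchart, which specifies no numeric cutoffs.")


def chance_upper_bound(n_test: int, alpha: float = 0.05) -> float:
    """Smallest accuracy k/n whose upper tail under Binomial(n, 0.5) is
    ≤ alpha; accuracies strictly above chance exceed this bound."""
    if n_test <= 0:
        raise ValueError("n_test must be positive")
    # smallest k with P(X >= k) <= alpha
    k = int(binom.isf(alpha, n_test, 0.5)) + 1
    return min(k, n_test) / n_test


@dataclass
class ContrastMetrics:
    """Accuracy of one contrast at each trial-averaging level.

    ``bacc_by_navg`` holds balanced accuracy — the mean of sensitivity and
    specificity — which stays centred at 0.5 under the null even when the
    test set is imbalanced (a majority-biased classifier inflates raw
    accuracy above 0.5 on, e.g., a 2:1 standard:deviant test set).  All
    chance comparisons use it when present; raw accuracy is kept for
    reporting.
    """

    acc_by_navg: dict[int, float]       # n_avg -> mean accuracy
    n_test_by_navg: dict[int, float]    # n_avg -> test-set size
    se_navg1: float                     # across-repeat SE at n_avg = 1
    gain_se: float | None = None        # across-repeat SE of the paired
                                        # per-repeat gain acc5 − acc1
    bacc_by_navg: dict[int, float] | None = None

    @property
    def accuracy(self) -> float:
        return self.acc_by_navg[1]

    @property
    def n_test(self) -> float:
        return self.n_test_by_navg[1]

    def decision_acc(self, n_avg: int) -> float:
        """Accuracy used for chance comparisons (balanced when available)."""
        if self.bacc_by_navg and n_avg in self.bacc_by_navg:
            return self.bacc_by_navg[n_avg]
        return self.acc_by_navg[n_avg]

    @property
    def gain(self) -> float:
        top = max(self.acc_by_navg)
        return self.decision_acc(top) - self.decision_acc(1)

    @property
    def gain_threshold(self) -> float:
        """Twice the SE of the gain (falling back to the single-trial SE
        when no paired estimate is available)."""
        se = self.gain_se if self.gain_se is not None else self.se_navg1
        return 2.0 * se

    def shifted(self, delta: float) -> "ContrastMetrics":
        bacc = ({k: min(1.0, v + delta) for k, v in self.bacc_by_navg.items()}
                if self.bacc_by_navg else None)
        return ContrastMetrics(
            {k: min(1.0, v + delta) for k, v in self.acc_by_navg.items()},
            dict(self.n_test_by_navg), self.se_navg1, self.gain_se, bacc)


@dataclass
class DecisionMetrics:
    """The three metric families for one subject."""

    m1: dict[str, ContrastMetrics]      # active-mode stimulus contrasts
    m2: dict[str, ContrastMetrics]      # active-vs-breathing per stimulus
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = []
        if not self.m1:
            missing.append("m1 (active-mode stimulus contrasts)")
        if not self.m2:
            missing.append("m2 (active-vs-breathing mode contrasts)")
        if missing:
            raise ValueError("incomplete decision metrics; missing: "
                             + ", ".join(missing))


@dataclass
class DecisionReport:
    verdict: str
    checks: dict
    alpha: float
    notes: str = FORMALIZATION_NOTE
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"verdict: {self.verdict} (alpha={self.alpha})"]
        for name, c in self.checks.items():
            lines.append(f"  {name}: {c}")
        lines.append(f"note: {self.notes}")
        return "\n".join(lines)


def _passes(cm: ContrastMetrics, n_avg: int, alpha: float) -> bool:
    if n_avg not in cm.acc_by_navg:
        return False
    n = int(round(cm.n_test_by_navg[n_avg]))
    if n <= 0:
        return False
    return cm.decision_acc(n_avg) > chance_upper_bound(n, alpha)


def detect(metrics: DecisionMetrics, alpha: float = 0.05) -> DecisionReport:
    """Apply the three-metric decision ladder. See the module docstring."""
    metrics.validate()
    checks: dict = {}

    # (a) m1 at single trials, then re-tested at higher averaging levels
    m1_single = {k: _passes(cm, 1, alpha) for k, cm in metrics.m1.items()}
    m1_avg = {
        k: any(_passes(cm, n, alpha) for n in sorted(cm.acc_by_navg) if n > 1)
        for k, cm in metrics.m1.items()}
    m1_pass = any(m1_single.values()) or any(m1_avg.values())
    checks["m1_single_trial"] = m1_single
    checks["m1_trial_averaged"] = m1_avg

    # (b)/(c) m2 bounds and m3 gains
    m2_pass_by = {k: _passes(cm, 1, alpha) for k, cm in metrics.m2.items()}
    m2_pass = any(m2_pass_by.values())
    checks["m2"] = m2_pass_by

    gains = {k: (cm.gain, cm.gain_threshold)
             for k, cm in {**metrics.m1, **metrics.m2}.items()
             if len(cm.acc_by_navg) > 1}
    checks["m3_gain"] = {k: {"gain": g, "threshold": thr, "pass": g > thr}
                         for k, (g, thr) in gains.items()}
    # the gain-based path to detection considers the mode contrasts: a
    # borderline m2 redeemed by a genuine trial-averaging gain
    m3_m2_positive = any(cm.gain > cm.gain_threshold
                         for cm in metrics.m2.values()
                         if len(cm.acc_by_navg) > 1)

    if not m1_pass:
        verdict = "no_evidence"
    elif m2_pass or m3_m2_positive:
        verdict = "consciousness_detected"
    else:
        verdict = "potentially_conscious"
    return DecisionReport(verdict, checks, alpha,
                          provenance=dict(metrics.provenance))
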