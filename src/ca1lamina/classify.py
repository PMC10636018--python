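"""Putative cell-class assignment: CA1 pyramidal vs. interneuron.

Replicates the manual rule set (anatomical gate, 7 Hz firing-rate rule with
an autocorrelogram-based guard band near the boundary) and the automated
k-means (k = 2) cross-check, plus the agreement report between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .types import LAYER_BELOW_PYR, LAYER_CA1_PYR, UnitMetrics

PYRAMIDAL = "pyramidal"
INTERNEURON = "interneuron"
DENTATE_EXCLUDED = "dentate_excluded"
UNCLASSIFIABLE = "unclassifiable"

RATE_BOUNDARY_HZ = 7.0  # pyramidal at or below, interneuron above
GUARD_BAND_HZ = 1.0  # refinement applies within +/- 1 Hz of the boundary

__all__ = [
    "anatomical_gate",
    "classify_manual",
    "classify_manual_table",
    "classify_kmeans",
    "compare_classifications",
]


def anatomical_gate(units: list[UnitMetrics]) -> tuple[list[UnitMetrics], dict[str, str]]:
    """Partition units by probe position.

    Units recorded below the annotated CA1 pyramidal layer (the bottom
    portion of the probe, toward dentate) are excluded as putative dentate
    cells; the rest pass to the rate/waveform rules. Units with no layer
    annotation are unclassifiable.
    """
    passed: list[UnitMetrics] = []
    labels: dict[str, str] = {}
    for m in units:
        if not m.layer:
            warnings.warn(f"unit {m.unit_id}: missing layer label", stacklevel=2)
            labels[m.unit_id] = UNCLASSIFIABLE
        elif m.layer == LAYER_BELOW_PYR:
            labels[m.unit_id] = DENTATE_EXCLUDED
        else:
            passed.append(m)
    return passed, labels


def classify_manual(
    metrics: UnitMetrics, fm_median: float | None = None
) -> str:
    """Rate-rule classification of one gated unit.

    Primary rule: firing rate at or below 7 Hz -> pyramidal, above 7 Hz ->
    interneuron. Refinement (deterministic stand-in for the manual
    waveform/autocorrelogram review): for calls within 1 Hz of the boundary,
    a first moment of the autocorrelogram on the wrong side of the
    population median (``fm_median``) makes the unit unclassifiable —
    pyramidal cells fire in bursts and have a small first moment, tonic
    interneurons a large one.
    """
    rate = metrics.firing_rate
    if not np.isfinite(rate) or not np.isfinite(metrics.acg_first_moment):
        return UNCLASSIFIABLE
    label = PYRAMIDAL if rate <= RATE_BOUNDARY_HZ else INTERNEURON
    if fm_median is not None and abs(rate - RATE_BOUNDARY_HZ) <= GUARD_BAND_HZ:
        fm = metrics.acg_first_moment
        if label == PYRAMIDAL and fm > fm_median:
            return UNCLASSIFIABLE
        if label == INTERNEURON and fm <= fm_median:
            return UNCLASSIFIABLE
    return label


def classify_manual_table(units: list[UnitMetrics]) -> dict[str, str]:
    """Anatomical gate plus rate-rule classification for a unit table."""
    passed, labels = anatomical_gate(units)
    fms = [m.acg_first_moment for m in passed if np.isfinite(m.acg_first_moment)]
    fm_median = float(np.median(fms)) if fms else None
    for m in passed:
        labels[m.unit_id] = classify_manual(m, fm_median=fm_median)
    return labels


@dataclass
class KMeansResult:
    labels: dict[str, str]
    centroids: pd.DataFrame  # feature means per cluster, original units
    silhouette: float


def classify_kmeans(units: list[UnitMetrics], seed: int = 0) -> KMeansResult:
    """Automated k-means (k = 2) classification of gated units.

    Features: log firing rate, spike width, autocorrelogram first moment,
    z-scored per feature. The cluster with the higher mean firing rate is
    labeled interneuron. Deterministic for a fixed seed; invariant to unit
    order (10 k-means++ restarts).
    """
    passed, labels = anatomical_gate(units)
    if len(passed) < 2:
        raise ValueError("k-means needs at least 2 gated units")
    feats = np.array(
        [
            [np.log(max(m.firing_rate, 1e-3)), m.spike_width, m.acg_first_moment]
            for m in passed
        ]
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    rates = np.array([m.firing_rate for m in passed])
    mean_rates = [rates[km.labels_ == k].mean() for k in (0, 1)]
    int_cluster = int(np.argmax(mean_rates))
    for m, k in zip(passed, km.labels_):
        labels[m.unit_id] = INTERNEURON if k == int_cluster else PYRAMIDAL
    cent = pd.DataFrame(
        km.cluster_centers_ * sd + mu,
        columns=["log_rate", "spike_width_ms", "acg_first_moment_ms"],
        index=[
            INTERNEURON if k == int_cluster else PYRAMIDAL for k in (0, 1)
        ],
    )
    sil = float(silhouette_score(z, km.labels_)) if len(passed) > 2 else np.nan
    return KMeansResult(labels=labels, centroids=cent, silhouette=sil)


@dataclass
class AgreementReport:
    confusion: pd.DataFrame
    percent_agreement: float
    disagreements: list[str]
    low_agreement: bool


def compare_classifications(
    manual: dict[str, str], kmeans: dict[str, str], warn_below: float = 80.0
) -> AgreementReport:
    """Confusion matrix and percent agreement between manual and k-means
    labelings of the same unit set (excluded/unclassifiable units are
    compared as-is)."""
    if set(manual) != set(kmeans):
        raise ValueError("manual and k-means labelings cover different unit sets")
    ids = sorted(manual)
    a = pd.Series({u: manual[u] for u in ids}, name="manual")
    b = pd.Series({u: kmeans[u] for u in ids}, name="kmeans")
    confusion = pd.crosstab(a, b)
    agree = float((a == b).mean() * 100.0)
    return AgreementReport(
        confusion=confusion,
        percent_agreement=agree,
        disagreements=[u for u in ids if manual[u] != kmeans[u]],
        low_agreement=agree < warn_below,
    )
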