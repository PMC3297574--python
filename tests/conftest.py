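"""Shared fixtures: small PWMs, planted-signal training sets, and a
session-scoped synthetic study matching the package's default conditions
(40 positives with 3 signal PWMs, 1000 matched controls, 50 decoy PWMs)."""

from __future__ import annotations

import numpy as np
import pytest

import cisclassify as cc


@pytest.fixture(scope="session")
def signal_pwms():
    return cc.make_random_pwms(3, seed=11, prefix="signal")


@pytest.fixture(scope="session")
def decoy_pwms():
    return cc.make_random_pwms(50, seed=12, prefix="decoy")


@pytest.fixture(scope="session")
def world(signal_pwms, decoy_pwms):
    return cc.build_synthetic_world(
        2, 100_000, 90, 20, signal_pwms, decoy_pwms, seed=21
    )


@pytest.fixture(scope="session")
def study(signal_pwms, decoy_pwms, world):
    """Positives, matched controls and the feature matrix under the default
    study conditions."""
    positives, placements = cc.make_positives(40, signal_pwms, seed=13)
    exclusions = [
        cds for g in world.annotations for cds in g.cds_intervals
    ] + list(world.planted_enhancers)
    controls = cc.sample_matched_controls(
        positives, world.genome, exclusions, n=1000, seed=14
    )
    pwms = list(signal_pwms) + list(decoy_pwms)
    features = cc.build_feature_matrix(
        positives + controls,
        pwms,
        labels=[1] * len(positives) + [-1] * len(controls),
    )
    return {
        "positives": positives,
        "placements": placements,
        "controls": controls,
        "exclusions": exclusions,
        "pwms": pwms,
        "features": features,
    }


def point_mass_pwm(consensus: str, pwm_id: str = "pm") -> cc.Pwm:
    """Near-point-mass PWM whose consensus is the given word."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus):
        counts[i, idx[c]] = 100.0
    return cc.Pwm.from_counts(pwm_id, counts, pseudocount=0.01)
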