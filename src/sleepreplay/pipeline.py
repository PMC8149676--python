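"""Participant-level orchestration of the full analysis on simulated data.

One participant contributes two sessions with counterbalanced learning
categories. Per session the stages are:

1. simulate the nap and the localizer;
2. linked-mastoid re-reference → SO + spindle detection on Cz over
   movement-free N2/N3 → SO-spindle pairing (spindle within 1.5 s of the
   downstate);
3. downstate-locked Cz epochs (±2.5 s) → per-event coupling phase;
4. common-average re-reference → downstate-locked epochs (±1.5 s) for
   decoding, labelled with the session's learned category.

Sessions are then pooled: the localizer decoder is trained on the
concatenated localizer data and tested on the concatenated sleep epochs
(temporal generalization), exactly as the two-class structure requires —
above-chance AUC means sleep activity resembles the just-learned category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet
from .coupling import event_coupling_phase, participant_coupling, CouplingResult
from .decoding import DecodingMap, preprocess_for_decoding, temporal_generalization
from .events import detect_slow_oscillations, detect_spindles, pair_so_spindle
from .io import extract_epochs, rereference
from .simulate import GroundTruth, SimConfig, simulate_localizer, simulate_sleep_recording

#: Amplitude criteria used when validating detection against planted ground
#: truth (see events module docstrings): SO troughs must exceed 3 robust
#: noise SDs; spindle RMS peaks must reach twice the percentile threshold.
VALIDATION_SO_SD_FACTOR = 3.0
VALIDATION_SPINDLE_PEAK_FACTOR = 2.0

#: Spindle anchor for SO-spindle pairing in this pipeline. The coupling
#: phase is defined at the spindle envelope maximum, so anchoring the 1.5-s
#: pairing window on the same feature keeps the paired set free of phase
#: censoring (onset-anchored pairing drops spindles peaking near the
#: downstate, biasing preferred phases toward the upstate).
PAIRING_ANCHOR = "amplitude_peak_time"


def _concat_epochs(sets: list[EpochSet]) -> EpochSet:
    ref = sets[0]
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        times=ref.times,
        lock=ref.lock,
        channel_names=list(ref.channel_names),
        labels=np.concatenate([s.labels for s in sets]),
        channel_positions=ref.channel_positions,
        participant=ref.participant,
    )


@dataclass
class ParticipantResult:
    """Pooled two-session outcome for one simulated participant.

    ``localizer``/``sleep`` hold the preprocessed component-space epochs;
    cohort-level analyses drop them (None) to bound memory at ~100 MB per
    participant otherwise retained.
    """

    localizer: EpochSet | None  # preprocessed, component space
    sleep: EpochSet | None  # preprocessed, component space
    decoding_map: DecodingMap
    coupling: CouplingResult
    truths: list[GroundTruth]
    n_complexes: int


def analyze_participant(
    cfg: SimConfig,
    participant: int,
    n_shuffles: int = 250,
    train_step: int = 1,
    test_step: int = 1,
    channel: str = "Cz",
    random_state: int | None = None,
) -> ParticipantResult:
    """Run the full detection → coupling → decoding pipeline on one participant."""
    loc_sets, sleep_sets, cz_sets, truths = [], [], [], []
    n_complexes = 0
    for session in (0, 1):
        eeg, mask, truth = simulate_sleep_recording(cfg, participant, session)
        truths.append(truth)
        eeg_lm = rereference(eeg, "linked-mastoids")
        sos = detect_slow_oscillations(
            eeg_lm, mask, channel, amplitude_sd_factor=VALIDATION_SO_SD_FACTOR
        )
        spindles = detect_spindles(
            eeg_lm, mask, channel, min_peak_factor=VALIDATION_SPINDLE_PEAK_FACTOR
        )
        pairing = pair_so_spindle(sos, spindles, anchor=PAIRING_ANCHOR)
        downstates = np.array([c.so.downstate for c in pairing.complexes])
        n_complexes += downstates.size

        cz_sets.append(
            extract_epochs(
                eeg_lm, downstates, (-2.5, 2.5), lock="SO-downstate", channels=[channel]
            )
        )
        eeg_car = rereference(eeg, "common-average")
        sleep_ep = extract_epochs(eeg_car, downstates, (-1.5, 1.5), lock="SO-downstate")
        sleep_ep.labels = np.full(sleep_ep.n_events, truth.session_category)
        sleep_sets.append(sleep_ep)

        loc = simulate_localizer(cfg, participant, session)
        loc.data = rereference_epochs_car(loc.data)
        loc_sets.append(loc)

    localizer = _concat_epochs(loc_sets)
    sleep = _concat_epochs(sleep_sets)

    phases = np.concatenate([event_coupling_phase(c, channel=channel) for c in cz_sets])
    coupling = participant_coupling(phases)

    loc_p, sleep_p, _, _ = preprocess_for_decoding(localizer, sleep)
    dmap = temporal_generalization(
        loc_p,
        sleep_p,
        n_shuffles=n_shuffles,
        train_step=train_step,
        test_step=test_step,
        random_state=random_state,
    )
    return ParticipantResult(
        localizer=loc_p,
        sleep=sleep_p,
        decoding_map=dmap,
        coupling=coupling,
        truths=truths,
        n_complexes=n_complexes,
    )


def rereference_epochs_car(data: np.ndarray) -> np.ndarray:
    """Common-average re-reference epoch data (events × channels × time)."""
    return data - data.mean(axis=1, keepdims=True)


@dataclass
class CohortResult:
    """Group-level outcome of the simulated study."""

    participants: list[ParticipantResult]
    observed: np.ndarray  # (n, train, test) AUC maps
    surrogate: np.ndarray  # matching surrogate baselines
    cluster: "object"  # ClusterResult of observed vs surrogate
    preferred_phases: np.ndarray
    reactivation_strength: np.ndarray  # mean AUC over the significant cluster
    behavior: "object"  # BehaviorTable (DataFrame)
    retention_index: np.ndarray


def analyze_cohort(
    cfg: SimConfig,
    n_shuffles: int = 250,
    train_step: int = 1,
    test_step: int = 1,
    n_permutations: int = 1000,
    random_state: int = 0,
) -> CohortResult:
    """Full group analysis: decoding maps, cluster test, coupling, behavior.

    Reactivation strength is the mean AUC over the significant *positive*
    cluster (above-chance decoding; below-chance stripes induced by
    whole-trial baselining are excluded). When no positive cluster reaches
    significance, the union of positive supra-threshold clusters is used —
    the participant-level scalar correlated with coupling phase and with the
    behavioral retention index.
    """
    from .simulate import simulate_behavior
    from .stats import cluster_permutation, reactivation_strength, recall_and_retention

    results = []
    for p in range(cfg.n_participants):
        r = analyze_participant(
            cfg,
            p,
            n_shuffles=n_shuffles,
            train_step=train_step,
            test_step=test_step,
            random_state=random_state + p,
        )
        r.localizer = r.sleep = None  # free the epoch arrays, keep summaries
        results.append(r)
    observed = np.stack([r.decoding_map.auc for r in results])
    surrogate = np.stack([r.decoding_map.surrogate_auc for r in results])
    cluster = cluster_permutation(
        observed, surrogate, n_permutations=n_permutations, random_state=random_state
    )
    mask = cluster.significant_mask(sign="positive")
    if not mask.any():
        for m, stat in zip(cluster.cluster_masks, cluster.cluster_stats):
            if stat > 0:
                mask |= m
    strength = (
        reactivation_strength(observed, mask=mask)
        if mask.any()
        else observed.mean(axis=(1, 2))
    )
    phases = np.array([r.coupling.preferred_phase for r in results])
    planted_mus = np.array([r.truths[0].participant_mu for r in results])
    behavior, _ = simulate_behavior(cfg, planted_mus)
    scores = recall_and_retention(behavior)
    return CohortResult(
        participants=results,
        observed=observed,
        surrogate=surrogate,
        cluster=cluster,
        preferred_phases=phases,
        reactivation_strength=strength,
        behavior=behavior,
        retention_index=scores["retention_index"].to_numpy(),
    )
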