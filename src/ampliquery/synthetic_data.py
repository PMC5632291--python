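"""Synthetic amplicon surveys with planted sequence-category associations.

The generator emulates the statistical structure the enrichment tests
assume: samples carry independent categorical metadata, every feature is
present in a sample with some probability, and read counts are drawn
multinomially over the present features at a per-sample sequencing
depth. A *planted effect* raises a feature's presence probability and/or
mean relative frequency inside one metadata category, giving the
binomial (presence channel) and ranksum (frequency channel) tests
distinct, known signals to recover.

What this deliberately does not model: ecological covariance between
taxa, phylogenetic signal, or compositional artefacts — the samples are
exchangeable under the null, which is exactly what calibration tests
need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from ampliquery.core_tables import FeatureTable, SampleMetadata
from ampliquery.rarefaction import sample_rng

__all__ = ["PlantedEffect", "generate_survey", "synthetic_cohort_metadata"]

#: Default survey scale: small enough for seconds-scale tests while
#: leaving every category with dozens of samples.
DEFAULT_N_SAMPLES = 200
DEFAULT_N_FEATURES = 300
DEFAULT_DEPTH_RANGE = (2000, 8000)
DEFAULT_BACKGROUND_PRESENCE = 0.3

DEFAULT_FIELDS_SPEC: dict[str, dict[str, float]] = {
    "host": {"host_a": 0.25, "host_b": 0.25, "host_c": 0.25, "host_d": 0.25},
    "site": {"reef": 0.5, "lagoon": 0.3, "deep": 0.2},
}


@dataclass(frozen=True)
class PlantedEffect:
    """A known sequence-category association to plant in a survey.

    ``p_in``/``p_out`` are the feature's presence probabilities in
    samples with/without the category value; ``mean_freq_in`` and
    ``mean_freq_out`` are its expected relative frequencies when
    present.
    """

    feature_id: str
    field: str
    value: str
    p_in: float
    p_out: float
    mean_freq_in: float = 0.05
    mean_freq_out: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        for f in (self.mean_freq_in, self.mean_freq_out):
            if not (0.0 < f < 1.0):
                raise ValueError("mean frequencies must lie in (0, 1)")


def _validate(
    n_samples: int,
    fields_spec: Mapping[str, Mapping[str, float]],
    n_features: int,
    depth_range: tuple[int, int],
    effects: Sequence[PlantedEffect],
    feature_ids: Sequence[str],
) -> None:
    if n_samples < 1 or n_features < 1:
        raise ValueError("n_samples and n_features must be >= 1")
    lo, hi = depth_range
    if not (1 <= lo <= hi):
        raise ValueError("depth_range must satisfy 1 <= lo <= hi")
    for field, probs in fields_spec.items():
        total = float(sum(probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"field {field!r}: category probabilities sum to {total}")
    fid_set = set(feature_ids)
    if len({e.feature_id for e in effects}) > n_features:
        raise ValueError("more effect features than features")
    for e in effects:
        if e.field not in fields_spec:
            raise ValueError(f"effect references unknown field {e.field!r}")
        if e.value not in fields_spec[e.field]:
            raise ValueError(f"effect references unknown value {e.value!r}")
        if e.feature_id not in fid_set:
            raise ValueError(f"effect references unknown feature {e.feature_id!r}")


def generate_survey(
    n_samples: int = DEFAULT_N_SAMPLES,
    fields_spec: Mapping[str, Mapping[str, float]] | None = None,
    n_features: int = DEFAULT_N_FEATURES,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    effects: Sequence[PlantedEffect] = (),
    background_freq_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    background_presence: float = DEFAULT_BACKGROUND_PRESENCE,
    seed: int = 0,
) -> tuple[FeatureTable, SampleMetadata, list[PlantedEffect]]:
    """Simulate a categorical-metadata amplicon survey.

    Per sample: (1) metadata values are drawn independently per field
    from ``fields_spec`` (category -> probability); (2) each feature is
    present with its effect-determined probability (``p_in`` if the
    sample carries the effect's value, else ``p_out``) or, for
    background features, ``background_presence``; (3) a sequencing
    depth is drawn uniformly from ``depth_range`` and reads are drawn
    multinomially over the present features. Present planted features
    get expected relative frequency ``mean_freq_in``/``mean_freq_out``
    exactly; background features share the remainder proportionally to
    per-feature lognormal weights from ``background_freq_dist``.

    Each sample uses a random stream derived from ``(seed, sample_id)``,
    so the output is reproducible and independent of generation order.

    Returns
    -------
    (FeatureTable, SampleMetadata, list of PlantedEffect)
        The truth list is the ``effects`` argument, returned verbatim.
    """
    spec = dict(fields_spec) if fields_spec is not None else DEFAULT_FIELDS_SPEC
    feature_ids = [f"F{j + 1:04d}" for j in range(n_features)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    _validate(n_samples, spec, n_features, depth_range, effects, feature_ids)

    global_rng = np.random.default_rng(np.random.SeedSequence(seed))
    if background_freq_dist is None:
        background_freq_dist = lambda rng, size: rng.lognormal(0.0, 1.0, size)
    base_weights = np.asarray(background_freq_dist(global_rng, n_features), dtype=float)
    if base_weights.shape != (n_features,) or np.any(base_weights <= 0):
        raise ValueError("background_freq_dist must yield positive weights")

    effects_by_feature: dict[str, list[PlantedEffect]] = {}
    for e in effects:
        effects_by_feature.setdefault(e.feature_id, []).append(e)
    planted_idx = {fid: j for j, fid in enumerate(feature_ids) if fid in effects_by_feature}

    field_names = list(spec)
    cat_names = {f: list(spec[f]) for f in field_names}
    cat_probs = {f: np.array([spec[f][c] for c in cat_names[f]]) for f in field_names}

    counts = np.zeros((n_samples, n_features), dtype=np.int64)
    metadata: dict[str, dict[str, str]] = {f: {} for f in field_names}
    lo, hi = depth_range
    for i, sid in enumerate(sample_ids):
        rng = sample_rng(seed, sid)
        values = {
            f: cat_names[f][rng.choice(len(cat_names[f]), p=cat_probs[f])]
            for f in field_names
        }
        for f in field_names:
            metadata[f][sid] = values[f]
        p_present = np.full(n_features, background_presence)
        target_freq = np.zeros(n_features)
        for fid, fx_list in effects_by_feature.items():
            j = planted_idx[fid]
            # if several effects touch one feature, any matching value wins
            in_group = any(values[e.field] == e.value for e in fx_list)
            e0 = fx_list[0]
            p_present[j] = max(e.p_in for e in fx_list if values[e.field] == e.value) \
                if in_group else e0.p_out
            target_freq[j] = e0.mean_freq_in if in_group else e0.mean_freq_out
        present = rng.random(n_features) < p_present
        if not present.any():
            continue
        weights = np.where(present, base_weights, 0.0)
        planted_present = [j for j in planted_idx.values() if present[j]]
        if planted_present:
            m_total = float(target_freq[planted_present].sum())
            bg_mask = present.copy()
            bg_mask[planted_present] = False
            bg_sum = float(weights[bg_mask].sum())
            if m_total < 1.0 and bg_sum > 0:
                # scale planted weights so their normalised share is exact
                for j in planted_present:
                    weights[j] = target_freq[j] / (1.0 - m_total) * bg_sum
        probs = weights / weights.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, probs)

    table = FeatureTable(sample_ids, feature_ids, counts)
    md = SampleMetadata(sample_ids, metadata)
    return table, md, list(effects)


#: Published cohort composition of the global sponge survey this package
#: models: sample-type label -> number of specimens.
COHORT_COMPOSITION = {
    "sponge": 3569,
    "seawater": 370,
    "sediment": 65,
    "biofilm": 21,
    "algae": 1,
    "echinoderm": 1,
    "negative control": 6,
}


def synthetic_cohort_metadata(
    composition: Mapping[str, int] | None = None,
    field: str = "sample_type",
) -> SampleMetadata:
    """Synthetic stand-in for the survey's deposited sample metadata.

    Builds a :class:`SampleMetadata` whose ``sample_type`` field has
    exactly the published cohort composition (3569 sponge specimens,
    370 seawater, 65 sediment samples, etc. — 4033 samples in all), so
    metadata audits can be exercised at the survey's real scale without
    the deposited file. This is a synthetic reconstruction of the
    cohort *sizes* only; it carries none of the survey's other fields.
    """
    comp = dict(composition) if composition is not None else COHORT_COMPOSITION
    sample_ids: list[str] = []
    values: dict[str, str] = {}
    i = 0
    for sample_type, n in comp.items():
        for _ in range(n):
            i += 1
            sid = f"SMP{i:05d}"
            sample_ids.append(sid)
            values[sid] = sample_type
    return SampleMetadata(sample_ids, {field: values})
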