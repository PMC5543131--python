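"""Synthetic multi-platform cohorts with known lineage and subtype structure.

The generator emulates the situation the pipeline is built for: each sample
carries a dominant tissue-of-origin (lineage) signal and a weaker cross-lineage
subtype signal.  Per feature and sample the latent value is

    x = mu_lineage + nu_subtype + eps,    eps ~ Normal(0, noise_sd^2)

where ``mu`` is nonzero (+/- effect_lineage, sign fixed per feature x lineage)
only on that platform's lineage-affected features and ``nu`` is nonzero
(+/- effect_subtype, sign fixed per feature x subtype) only on the planted
subtype features.  Continuous platforms emit ``x`` directly; methylation emits
``logistic(x)`` so beta values stay strictly inside (0, 1); copy number
discretizes ``x`` at fixed latent cutpoints into thresholded calls {-2..2};
the mutation platform emits Bernoulli draws whose rate is a logistic function
of the latent signal, so subtype features mutate more often in their subtype.

Each platform draws from its own RNG stream keyed off the master seed, so
adding or removing a platform never perturbs the values generated for the
others.  Survival times are exponential with subtype-dependent hazards and
independent exponential censoring tuned to the requested censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import OmicsMatrix, ValidationError

# Latent cutpoints for thresholded copy-number calls: values below -2.5 become
# deep deletions (-2), above 2.5 high-level amplifications (+2); the wide
# outer bands keep high-level events sparse, as in thresholded SNP-array calls.
COPY_CUTPOINTS = (-2.5, -1.0, 1.0, 2.5)

# Baseline log-odds of a mutation; expit(-3) ~ 0.047 background mutation rate.
MUTATION_BASE_LOGIT = -3.0

# Baseline event hazard (per day); median survival ~700 days at hazard 1.
BASE_EVENT_RATE = 1.0 / 1000.0

# Fixed per-platform stream keys so streams are independent of platform order.
_PLATFORM_KEYS = {
    "mrna": 11,
    "mirna": 12,
    "protein": 13,
    "methylation": 14,
    "copynumber": 15,
    "mutation": 16,
}
_SURVIVAL_KEY = 101


def _default_features() -> dict[str, int]:
    return {
        "mrna": 500,
        "mirna": 150,
        "protein": 120,
        "methylation": 300,
        "copynumber": 200,
        "mutation": 80,
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe three lineages of 60 samples each sharing three
    cross-lineage subtypes, a 3-SD lineage shift on half the features and a
    1.5-SD subtype shift on 10% of them, against unit noise — a dominant
    tissue effect hiding a weaker shared-subtype effect.
    """

    n_lineages: int = 3
    samples_per_lineage: int = 60
    n_subtypes: int = 3
    features_per_platform: dict[str, int] = field(default_factory=_default_features)
    frac_lineage_features: float = 0.5
    frac_subtype_features: float = 0.1
    effect_lineage: float = 3.0
    effect_subtype: float = 1.5
    noise_sd: float = 1.0
    missing_platform_prob: float = 0.1
    call_flip_prob: float = 0.1
    subtype_hazards: tuple[float, ...] = (1.0, 1.8, 3.0)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1 or self.samples_per_lineage < 2:
            raise ValidationError("need >=1 lineages with >=2 samples each")
        if self.n_subtypes < 1:
            raise ValidationError("need >=1 subtypes")
        if self.n_subtypes > self.samples_per_lineage:
            raise ValidationError(
                "n_subtypes exceeds samples_per_lineage: cannot plant every "
                "subtype in every lineage"
            )
        for p in (self.missing_platform_prob, self.call_flip_prob, self.censor_rate):
            if not 0.0 <= p < 1.0:
                raise ValidationError("probabilities must lie in [0, 1)")
        for f in (self.frac_lineage_features, self.frac_subtype_features):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("feature fractions must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if len(self.subtype_hazards) != self.n_subtypes:
            raise ValidationError("subtype_hazards length must equal n_subtypes")
        if any(h <= 0 for h in self.subtype_hazards):
            raise ValidationError("hazards must be positive")
        unknown = set(self.features_per_platform) - set(_PLATFORM_KEYS)
        if unknown:
            raise ValidationError(f"unknown platforms in config: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Planted ground truth: labels per sample, affected features per platform."""

    lineage: dict[str, str]
    subtype: dict[str, str]
    lineage_features: dict[str, np.ndarray]
    subtype_features: dict[str, np.ndarray]


def _platform_rng(seed: int, platform: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _PLATFORM_KEYS[platform]]))


def simulate_cohort(
    config: SimConfig,
) -> tuple[dict[str, OmicsMatrix], pd.DataFrame, SimTruth]:
    """Generate one cohort: platform matrices, annotation table, ground truth.

    Subtypes are planted cyclically within each lineage so every subtype is
    represented in every lineage.  A sample can be missing from individual
    platforms but never from all of them.
    """
    cfg = config
    n = cfg.n_lineages * cfg.samples_per_lineage
    sample_ids = [
        f"L{l + 1}S{i + 1:03d}"
        for l in range(cfg.n_lineages)
        for i in range(cfg.samples_per_lineage)
    ]
    lineages = [f"lineage{l + 1}" for l in range(cfg.n_lineages)]
    lineage_of = {
        s: lineages[j // cfg.samples_per_lineage] for j, s in enumerate(sample_ids)
    }
    subtype_idx = np.array(
        [i % cfg.n_subtypes for _ in range(cfg.n_lineages) for i in range(cfg.samples_per_lineage)]
    )
    subtype_of = {s: f"s{subtype_idx[j] + 1}" for j, s in enumerate(sample_ids)}
    lin_idx = np.repeat(np.arange(cfg.n_lineages), cfg.samples_per_lineage)

    matrices: dict[str, OmicsMatrix] = {}
    lineage_features: dict[str, np.ndarray] = {}
    subtype_features: dict[str, np.ndarray] = {}
    drop_masks: dict[str, np.ndarray] = {}

    platforms = sorted(cfg.features_per_platform, key=lambda p: _PLATFORM_KEYS[p])
    for platform in platforms:
        p = cfg.features_per_platform[platform]
        rng = _platform_rng(cfg.seed, platform)
        n_lin = int(round(cfg.frac_lineage_features * p))
        n_sub = int(round(cfg.frac_subtype_features * p))
        perm = rng.permutation(p)
        lin_feats = np.sort(perm[:n_lin])
        sub_feats = np.sort(perm[n_lin : n_lin + n_sub])
        lineage_features[platform] = lin_feats
        subtype_features[platform] = sub_feats

        lin_signs = rng.choice((-1.0, 1.0), size=(n_lin, cfg.n_lineages))
        sub_signs = rng.choice((-1.0, 1.0), size=(len(sub_feats), cfg.n_subtypes))

        latent = rng.normal(0.0, cfg.noise_sd, size=(p, n))
        latent[lin_feats] += cfg.effect_lineage * lin_signs[:, lin_idx]
        latent[sub_feats] += cfg.effect_subtype * sub_signs[:, subtype_idx]

        if platform == "methylation":
            values = expit(latent)
        elif platform == "copynumber":
            values = (np.digitize(latent, COPY_CUTPOINTS) - 2).astype(float)
        elif platform == "mutation":
            rate = expit(latent + MUTATION_BASE_LOGIT)
            values = rng.binomial(1, rate).astype(float)
        else:
            values = latent

        drop_masks[platform] = rng.random(n) < cfg.missing_platform_prob
        feature_ids = [f"{platform}_f{i + 1:04d}" for i in range(p)]
        matrices[platform] = (feature_ids, values)  # assembled after rescue below

    # Never drop a sample from every platform: rescue into the first platform
    # (deterministic; no extra randomness).
    if platforms:
        all_dropped = np.logical_and.reduce([drop_masks[p] for p in platforms])
        drop_masks[platforms[0]][all_dropped] = False

    lineage_series = pd.Series(lineage_of)
    for platform in platforms:
        feature_ids, values = matrices[platform]
        keep = ~drop_masks[platform]
        df = pd.DataFrame(
            values[:, keep],
            index=feature_ids,
            columns=[s for s, k in zip(sample_ids, keep) if k],
        )
        matrices[platform] = OmicsMatrix(
            platform_id=platform, data=df, lineage=lineage_series.loc[df.columns]
        )

    # Survival: exponential event times with subtype-dependent hazards,
    # independent exponential censoring matched to the target censor fraction.
    srng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _SURVIVAL_KEY]))
    hazards = np.asarray(cfg.subtype_hazards, dtype=float)
    rate = BASE_EVENT_RATE * hazards[subtype_idx]
    event_times = srng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        crate = rate.mean() * cfg.censor_rate / (1.0 - cfg.censor_rate)
        censor_times = srng.exponential(1.0 / crate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lineage": [lineage_of[s] for s in sample_ids],
            "surv_time": time,
            "surv_event": event,
            "true_subtype": [subtype_of[s] for s in sample_ids],
        }
    ).set_index("sample_id", drop=False)

    truth = SimTruth(
        lineage=lineage_of,
        subtype=subtype_of,
        lineage_features=lineage_features,
        subtype_features=subtype_features,
    )
    return matrices, annotation, truth


def simulate_platform_calls(
    truth: SimTruth,
    n_platforms: int,
    call_flip_prob: float,
    missing_call_prob: float,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Noisy per-platform subtype calls for exercising COCA.

    Each platform reports the true subtype with probability
    ``1 - call_flip_prob``, otherwise a uniformly random *other* label; a call
    is absent with probability ``missing_call_prob`` (applied first).
    """
    if not truth.subtype:
        raise ValidationError("truth has no samples")
    if not 0.0 <= call_flip_prob < 1.0 or not 0.0 <= missing_call_prob < 1.0:
        raise ValidationError("call probabilities must lie in [0, 1)")
    labels = sorted(set(truth.subtype.values()))
    calls: dict[str, dict[str, str]] = {}
    for i in range(n_platforms):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 500 + i]))
        platform_calls: dict[str, str] = {}
        for sample in sorted(truth.subtype):
            if rng.random() < missing_call_prob:
                continue
            true = truth.subtype[sample]
            if len(labels) > 1 and rng.random() < call_flip_prob:
                others = [lb for lb in labels if lb != true]
                platform_calls[sample] = others[rng.integers(len(others))]
            else:
                platform_calls[sample] = true
        calls[f"platform{i + 1}"] = platform_calls
    return calls


def truth_table(truth: SimTruth) -> pd.DataFrame:
    """Flat sample table of the planted labels (for the `simulate` CLI)."""
    samples = sorted(truth.lineage)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "lineage": [truth.lineage[s] for s in samples],
            "subtype": [truth.subtype[s] for s in samples],
        }
    )
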