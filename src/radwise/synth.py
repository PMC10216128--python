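"""Synthetic proteomic-panel generator with planted signal structure.

Emulates the shape of a paired pre/post-treatment serum proteomics cohort:
each patient contributes one pre (label 0) and one post (label 1) sample;
abundances are log-normal (RFU-like positive values); a small planted set
of informative features gains a fixed log-space shift in post samples;
each informative feature drags along correlated redundant proxies; the
rest is independent noise.  A per-sample multiplicative jitter mimics
residual scale variation left after assay normalization.

Ground truth (which features are informative, and which proxy belongs to
which parent) is returned alongside but kept out of the FeatureTable the
selection pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import FeatureTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Generative parameters of a synthetic paired panel.

    Defaults mirror the cohort scale the pipeline targets: 82 patients
    (164 samples), a thousand-feature panel, 8 informative features each
    shifted by 0.8 in log-abundance after treatment, with 2 proxies per
    informative feature at correlation 0.9.
    """

    seed: int
    n_patients: int = 82
    n_features: int = 1000
    n_informative: int = 8
    effect_log_shift: float = 0.8
    n_proxies_per_informative: int = 2
    proxy_correlation: float = 0.9
    base_log_mean: float = 8.0
    base_log_sd: float = 1.0
    sample_scale_jitter_sd: float = 0.05

    def validate(self) -> None:
        planted = self.n_informative * (1 + self.n_proxies_per_informative)
        if planted > self.n_features:
            raise ValueError(
                f"{planted} planted features (informative + proxies) exceed "
                f"n_features={self.n_features}")
        if not 0 < self.proxy_correlation < 1:
            raise ValueError("proxy_correlation must lie in (0, 1)")
        if self.n_patients < 1 or self.n_informative < 0:
            raise ValueError("n_patients >= 1 and n_informative >= 0 required")


@dataclass
class GroundTruth:
    """Planted-structure annotation kept separate from the pipeline input."""

    informative: list[str]
    proxies: dict[str, str] = field(default_factory=dict)  # proxy -> parent

    @property
    def planted(self) -> list[str]:
        return self.informative + sorted(self.proxies)

    def recovers(self, selected: list[str]) -> float:
        """Fraction of informative signals recovered by a selected set.

        A proxy counts as recovering its parent signal.
        """
        if not self.informative:
            return float("nan")
        hit = {self.proxies.get(f, f) for f in selected}
        return sum(p in hit for p in self.informative) / len(self.informative)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"informative": self.informative, "proxies": self.proxies},
            indent=2, sort_keys=True) + "\n")


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one panel from the generative model described above.

    Returns the FeatureTable (2·n_patients samples, balanced pre/post
    labels, paired patient ids) and the planted-feature ground truth.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_patients
    p = spec.n_features
    is_post = np.repeat([0, 1], spec.n_patients)  # pre block then post block

    feat_mean = rng.normal(spec.base_log_mean, 0.5, size=p)
    log_vals = feat_mean + rng.normal(0.0, spec.base_log_sd, size=(n, p))

    informative_idx = list(range(spec.n_informative))
    log_vals[:, informative_idx] += (
        spec.effect_log_shift * is_post[:, None]
    )

    rho = spec.proxy_correlation
    proxies: dict[str, str] = {}
    next_col = spec.n_informative
    names = [f"F{j:04d}" for j in range(p)]
    for parent in informative_idx:
        parent_log = log_vals[:, parent]
        w = (parent_log - parent_log.mean()) / parent_log.std()
        for _ in range(spec.n_proxies_per_informative):
            eps = rng.normal(0.0, 1.0, size=n)
            log_vals[:, next_col] = (
                feat_mean[next_col]
                + spec.base_log_sd * (rho * w + np.sqrt(1 - rho**2) * eps)
            )
            proxies[names[next_col]] = names[parent]
            next_col += 1

    jitter = rng.normal(0.0, spec.sample_scale_jitter_sd, size=n)
    values = np.exp(log_vals + jitter[:, None])

    patient_ids = [f"P{i:03d}" for i in range(spec.n_patients)] * 2
    sample_ids = [f"P{i:03d}_pre" for i in range(spec.n_patients)] + \
                 [f"P{i:03d}_post" for i in range(spec.n_patients)]
    table = FeatureTable(
        values=values, feature_names=names, sample_ids=sample_ids,
        labels=is_post, patient_ids=patient_ids,
    )
    truth = GroundTruth(
        informative=[names[j] for j in informative_idx], proxies=proxies,
    )
    return table, truth


def spec_as_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)
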