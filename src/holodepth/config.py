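"""Run configuration: every analysis threshold in one overridable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass
class RunConfig:
    """All thresholds and sizes of a pipeline run.

    Threshold defaults are the study constants: void retention time
    40 s, QC CV 0.30, common-ASV mean relative abundance 0.25%, sister
    identity 97%, water-mass split 1000 m, VIP 1, pQ2 0.05, R2X 0.9,
    Q2 0.5, edge p 0.05, 4-of-5 consensus votes, prevalence 3 samples,
    top-10 compound links.
    """

    seed: int = 0

    # Thresholds
    void_rt_max: float = 40.0
    qc_cv_max: float = 0.30
    common_threshold: float = 0.0025
    sister_min_identity: float = 0.97
    water_mass_split: float = 1000.0
    vip_threshold: float = 1.0
    pq2_max: float = 0.05
    r2x_min: float = 0.9
    q2_min: float = 0.5
    edge_p_max: float = 0.05
    consensus_min_votes: int = 4
    prevalence_min_samples: int = 3
    link_top_k: int = 10
    trend_alpha: float = 0.05
    vif_threshold: float = 10.0

    # Permutation / resampling counts
    permanova_permutations: int = 999
    envfit_permutations: int = 199
    mantel_permutations: int = 999
    procrustes_permutations: int = 999
    opls_permutations: int = 200
    opls_cv_folds: int = 7
    opls_n_ortho: int = 1
    network_permutations: int = 100
    sparcc_bootstraps: int = 100

    # Synthetic-dataset sizes (per species)
    n_samples_per_species: int = 15
    n_asvs_hma: int = 120
    n_asvs_lma: int = 120
    n_features: int = 150
    n_pc_groups: int = 30
    n_qc: int = 8
    frac_responsive_asv: float = 0.3
    n_sister_pairs: int = 3
    asv_effect_size: float = 2.5
    frac_void: float = 0.1
    frac_high_cv: float = 0.1
    frac_responsive_feature: float = 0.25
    metadata_collinearity: float = 0.9

    # Battery design
    species: tuple = ("Gb_like_HMA", "Sf_like_HMA", "Wb_like_LMA")
    experiments: tuple = (
        ("HILIC", "positive"),
        ("HILIC", "negative"),
        ("RP", "positive"),
        ("RP", "negative"),
    )
    filters: tuple = ("cleaned", "pc_group", "ion")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = list(self.species)
        d["experiments"] = [list(e) for e in self.experiments]
        d["filters"] = list(self.filters)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "experiments" in raw:
            raw["experiments"] = tuple(tuple(e) for e in raw["experiments"])
        for key in ("species", "filters"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
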