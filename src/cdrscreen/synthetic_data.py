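"""Synthetic compound/disease worlds with a planted relationship rule.

Real inputs to the pipeline are (a) dense molecular-descriptor vectors,
(b) sparse non-negative symptom-weight vectors, and (c) a curated set of
positive pairs.  This module emulates all three so every stage is testable
without external databases.

Generative model: each compound ``c`` and disease ``d`` carries a latent
vector (``u_c``, ``v_d``; dimension ``n_latent``, standard normal).  Compound
descriptors are a fixed dense linear mixing of ``u_c`` plus Gaussian noise;
disease symptom vectors are a sparse non-negative mixing of ``v_d`` plus
noise, clipped at zero (mimicking co-occurrence-derived symptom weights).
The planted rule is

    P(positive | c, d) = sigmoid(signal_strength * <u_c, v_d> + offset)

with the offset calibrated on the realized grid so the expected positive
fraction equals ``positive_rate``; labels are then Bernoulli draws.  At
``signal_strength = 0`` labels are pure noise and any classifier is at
chance; at strong signal the grid is nearly separable in the latents.

Desk-scale defaults (200 x 40 grid, 64 compound / 32 disease features) keep
encoding plus CNN training to minutes on one CPU; reference-scale dimensions
(5270 / 322) are reachable through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from cdrscreen.dataset import PairLabel, write_pairs
from cdrscreen.descriptors import DescriptorTable, write_descriptor_table


@dataclass(frozen=True)
class SimConfig:
    n_compounds: int = 200
    n_diseases: int = 40
    d_compound: int = 64
    d_disease: int = 32
    n_latent: int = 4
    signal_strength: float = 5.0
    noise_sd: float = 0.5
    positive_rate: float = 0.15
    symptom_density: float = 0.3   # fraction of nonzero entries in the mixing
    qc_rate: float = 0.2
    blood_rate: float = 0.2
    ob_mean: float = 30.0          # lognormal-ish spread around the filter cut
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_diseases", "d_compound", "d_disease",
                     "n_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.noise_sd <= 0 or self.signal_strength < 0:
            raise ValueError("noise_sd must be > 0 and signal_strength >= 0")


@dataclass
class SyntheticWorld:
    compounds: DescriptorTable
    diseases: DescriptorTable
    labels: pd.DataFrame        # one row per grid pair: ids, label, true_prob
    latents: dict[str, np.ndarray]
    config: SimConfig

    @property
    def positive_pairs(self) -> list[PairLabel]:
        pos = self.labels[self.labels["label"] == "positive"]
        return [
            PairLabel(r.compound_id, r.disease_id, "positive")
            for r in pos.itertuples()
        ]

    @property
    def true_scores(self) -> pd.Series:
        return self.labels.set_index(["compound_id", "disease_id"])["true_score"]


def _calibrate_offset(scores: np.ndarray, rate: float) -> float:
    """Offset making the mean sigmoid over the realized grid equal the rate."""

    def excess(offset: float) -> float:
        return float(expit(scores + offset).mean() - rate)

    lo, hi = -50.0, 50.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ValueError(
            "cannot calibrate the positive rate: planted scores too extreme"
        )
    return float(brentq(excess, lo, hi, xtol=1e-10))


def simulate(config: SimConfig) -> SyntheticWorld:
    """Draw a complete world (tables, latents, full labeled grid) from a seed."""
    rng = np.random.default_rng(config.seed)
    nc, nd, k = config.n_compounds, config.n_diseases, config.n_latent

    u = rng.standard_normal((nc, k))
    v = rng.standard_normal((nd, k))

    mix_c = rng.standard_normal((k, config.d_compound))
    x_c = u @ mix_c + config.noise_sd * rng.standard_normal((nc, config.d_compound))

    mix_d = np.abs(rng.standard_normal((k, config.d_disease)))
    mix_d *= rng.random((k, config.d_disease)) < config.symptom_density
    x_d = v @ mix_d + config.noise_sd * rng.standard_normal((nd, config.d_disease))
    x_d = np.clip(x_d, 0.0, None)  # symptom weights are non-negative

    raw = u @ v.T  # (nc, nd) planted affinity
    scores = config.signal_strength * raw
    offset = _calibrate_offset(scores.ravel(), config.positive_rate)
    probs = expit(scores + offset)
    drawn = rng.random((nc, nd)) < probs

    compound_ids = [f"cmp{i:04d}" for i in range(nc)]
    disease_ids = [f"dis{j:03d}" for j in range(nd)]

    annotations = pd.DataFrame(
        {
            "is_qc": rng.random(nc) < config.qc_rate,
            "is_blood": rng.random(nc) < config.blood_rate,
            "ob_percent": np.round(
                config.ob_mean * np.exp(rng.normal(0.0, 0.5, size=nc)), 2
            ),
        },
        index=pd.Index(compound_ids, name="compound_id"),
    )
    compounds = DescriptorTable(
        entity="compound",
        values=pd.DataFrame(
            x_c,
            index=pd.Index(compound_ids, name="compound_id"),
            columns=[f"desc_{i:03d}" for i in range(config.d_compound)],
        ),
        annotations=annotations,
    )
    diseases = DescriptorTable(
        entity="disease",
        values=pd.DataFrame(
            x_d,
            index=pd.Index(disease_ids, name="disease_id"),
            columns=[f"symp_{i:03d}" for i in range(config.d_disease)],
        ),
    )
    ci, di = np.meshgrid(np.arange(nc), np.arange(nd), indexing="ij")
    labels = pd.DataFrame(
        {
            "compound_id": [compound_ids[i] for i in ci.ravel()],
            "disease_id": [disease_ids[j] for j in di.ravel()],
            "label": np.where(drawn.ravel(), "positive", "negative"),
            "true_prob": probs.ravel(),
            "true_score": raw.ravel(),
        }
    )
    return SyntheticWorld(
        compounds=compounds,
        diseases=diseases,
        labels=labels,
        latents={"u": u, "v": v, "offset": np.array([offset])},
        config=config,
    )


def world_to_tables(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write compounds.csv / diseases.csv / pairs.csv in the package dialect.

    The ground-truth probabilities go to a separate truth.csv so training code
    paths can consume the three input tables without seeing the answer key.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.csv",
        "diseases": out / "diseases.csv",
        "pairs": out / "pairs.csv",
        "truth": out / "truth.csv",
    }
    write_descriptor_table(world.compounds, paths["compounds"])
    write_descriptor_table(world.diseases, paths["diseases"])
    write_pairs(
        [
            PairLabel(r.compound_id, r.disease_id, r.label)
            for r in world.labels.itertuples()
        ],
        paths["pairs"],
    )
    world.labels[["compound_id", "disease_id", "true_prob", "true_score"]].to_csv(
        paths["truth"], index=False
    )
    return paths
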