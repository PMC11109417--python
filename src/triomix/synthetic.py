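"""Synthetic two-group multi-omic studies with planted ground truth.

The generator emulates the *outputs* of an amplicon + GC-MS workflow on a
case/control stool cohort: two compositional count blocks (bacteria, fungi)
with uneven sequencing depth, one continuous concentration block
(metabolites), group-differential "marker" features planted at a known fold
change, and bacterium-fungus pairs coupled through a Gaussian copula at a
known Spearman correlation.  Every downstream stage can therefore be scored
against :class:`SyntheticTruth` without the deposited cohort.

Model per omic: feature i has a log-normal base abundance
``a_ij = exp(mu_i + sigma * z_ij)`` with ``mu_i ~ N(0, 1.5)`` and iid
standard-normal latents ``z_ij``.  Planted markers are multiplied by
``effect_size`` in their enriched group.  Count blocks are drawn per sample
as ``Multinomial(depth_j, a_.j / sum a_.j)`` with depth uniform over
``depth_range``; metabolites keep the continuous abundances (mg/kg scale).
Planted cross-kingdom pairs replace the two features' latents by a
bivariate normal with Pearson correlation ``2 sin(pi * rho / 6)``, the
Gaussian-copula value whose rank correlation is ``rho``; rank correlations
survive the monotone exp transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AlignedStudy, FeatureTable, write_feature_table, write_metadata

# latent geometry shared by every omic
_MU_SD = 1.5          # spread of log base abundances across features
_NOISE_SD = 1.0       # per-sample log-abundance noise
_EDGE_MU_BOOST = 1.0  # planted-edge features are made abundant so that
                      # multinomial count noise does not mask the copula
_EDGE_NOISE_SD = 2.0  # and given a wide dynamic range so compositional
                      # closure noise does not attenuate the planted rank
                      # correlation


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the cohort the package is designed around: 53 UC vs 37
    CTRL samples, ~200 bacterial and ~50 fungal taxa, 95 metabolites, and a
    4-fold planted group effect.
    """

    n_uc: int = 53
    n_ctrl: int = 37
    n_features: dict = field(
        default_factory=lambda: {"bacteria": 200, "fungi": 50, "metabolite": 95}
    )
    n_markers: dict = field(
        default_factory=lambda: {"bacteria": 20, "fungi": 6, "metabolite": 12}
    )
    effect_size: float = 4.0
    depth_range: tuple = (5000, 50000)
    n_planted_edges: int = 8
    copula_rho: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_uc < 2 or self.n_ctrl < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not -1 < self.copula_rho < 1:
            raise ValueError("copula_rho must lie in (-1, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        for omic in ("bacteria", "fungi", "metabolite"):
            if omic not in self.n_features or omic not in self.n_markers:
                raise ValueError(f"config must cover omic {omic!r}")
            if self.n_markers[omic] > self.n_features[omic]:
                raise ValueError(f"{omic}: more planted markers than features")
        for omic in ("bacteria", "fungi"):
            if self.n_markers[omic] + self.n_planted_edges > self.n_features[omic]:
                raise ValueError(
                    f"{omic}: markers + planted edges exceed feature count"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth: marker ids with direction, copula edge list."""

    markers: dict  # omic -> {feature_id: "UC" | "CTRL"} (enriched group)
    edges: list    # (bacterium_id, fungus_id, sign)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


_PREFIX = {"bacteria": "bact", "fungi": "fung", "metabolite": "voc"}


def _feature_ids(omic: str, n: int) -> list[str]:
    return [f"{_PREFIX[omic]}_{i:03d}" for i in range(n)]


def _marker_directions(ids: list[str]) -> dict[str, str]:
    # alternate enrichment so both groups carry markers
    return {fid: ("UC" if k % 2 == 0 else "CTRL") for k, fid in enumerate(ids)}


def generate_study(config: SyntheticConfig) -> tuple[AlignedStudy, SyntheticTruth]:
    """Simulate one aligned three-block study plus its planted truth.

    Identical config (including seed) gives bit-identical output.  The seed
    feeds a hierarchical stream with one substream per omic plus one for the
    copula and one for metadata, so adding features to one omic does not
    perturb the others.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("bacteria", "fungi", "metabolite", "copula", "metadata"), root.spawn(5)
        )
    }
    n = config.n_uc + config.n_ctrl
    sample_ids = [f"UC{i + 1:03d}" for i in range(config.n_uc)] + [
        f"CTRL{i + 1:03d}" for i in range(config.n_ctrl)
    ]
    is_uc = np.array([s.startswith("UC") for s in sample_ids])

    # plant markers (first features of each omic) and copula edges (the
    # following features of bacteria/fungi, disjoint from markers)
    ids = {omic: _feature_ids(omic, config.n_features[omic]) for omic in _PREFIX}
    markers = {
        omic: _marker_directions(ids[omic][: config.n_markers[omic]]) for omic in _PREFIX
    }
    nb, nf = config.n_markers["bacteria"], config.n_markers["fungi"]
    edges = [
        (
            ids["bacteria"][nb + k],
            ids["fungi"][nf + k],
            1 if k % 2 == 0 else -1,
        )
        for k in range(config.n_planted_edges)
    ]

    # copula latents for the planted pairs, shared across the two omics
    rho_pearson = 2.0 * np.sin(np.pi * config.copula_rho / 6.0)
    z_b = streams["copula"].standard_normal((config.n_planted_edges, n))
    z_noise = streams["copula"].standard_normal((config.n_planted_edges, n))
    edge_latents = {}
    for k, (bid, fid, sign) in enumerate(edges):
        r = sign * rho_pearson
        z_f = r * z_b[k] + np.sqrt(1.0 - r * r) * z_noise[k]
        edge_latents[bid] = z_b[k]
        edge_latents[fid] = z_f

    blocks: dict[str, FeatureTable] = {}
    for omic in _PREFIX:
        rng = streams[omic]
        p = config.n_features[omic]
        mu = rng.normal(0.0, _MU_SD, size=p)
        z = rng.standard_normal((p, n))
        sigma = np.full(p, _NOISE_SD)
        for i, fid in enumerate(ids[omic]):
            if fid in edge_latents:
                z[i] = edge_latents[fid]
                mu[i] += _EDGE_MU_BOOST
                sigma[i] = _EDGE_NOISE_SD
        log_abund = mu[:, None] + sigma[:, None] * z
        for i, fid in enumerate(ids[omic]):
            direction = markers[omic].get(fid)
            if direction is None:
                continue
            enriched = is_uc if direction == "UC" else ~is_uc
            log_abund[i, enriched] += np.log(config.effect_size)
        abund = np.exp(log_abund)
        if omic == "metabolite":
            values = abund  # concentrations, mg/kg scale
            kind = "concentration"
        else:
            depths = rng.integers(
                config.depth_range[0], config.depth_range[1] + 1, size=n
            )
            probs = abund / abund.sum(axis=0, keepdims=True)
            values = np.column_stack(
                [rng.multinomial(depths[j], probs[:, j]) for j in range(n)]
            )
            kind = "count"
        df = pd.DataFrame(values, index=ids[omic], columns=sample_ids)
        blocks[omic] = FeatureTable(df, omic=omic, value_kind=kind)

    metadata = _simulate_metadata(sample_ids, is_uc, streams["metadata"])
    study = AlignedStudy(blocks, metadata, list(sample_ids))
    return study, SyntheticTruth(markers=markers, edges=edges)


def _simulate_metadata(sample_ids, is_uc, rng) -> pd.DataFrame:
    """Cohort covariates: age/gender roughly matched, therapy flags UC-only."""
    n = len(sample_ids)
    age = np.where(
        is_uc, rng.normal(40.5, 14.1, size=n), rng.normal(50.7, 14.8, size=n)
    )
    age = np.clip(np.round(age), 18, 85)
    gender = np.where(rng.random(n) < 0.47, "M", "F")
    therapy = {
        "corticosteroid_therapy": 0.77,
        "previous_therapy": 0.40,
        "failure_previous_therapies": 0.34,
    }
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_uc, "UC", "CTRL"),
            "gender": gender,
            "age": age,
        }
    )
    for col, rate in therapy.items():
        flags = rng.random(n) < rate
        df[col] = pd.array(np.where(is_uc, flags, None), dtype="boolean")
    return df.set_index("sample_id", drop=False)


def write_study(study: AlignedStudy, truth: SyntheticTruth, out_dir) -> None:
    """Write the three TSV tables, metadata CSV, and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, block in study.blocks.items():
        write_feature_table(block, out / f"{name}.tsv")
    write_metadata(study.metadata, out / "metadata.csv")
    (out / "truth.json").write_text(truth.to_json())
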