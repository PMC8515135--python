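"""Paired human/mouse synthetic expression with planted cross-species structure.

The generator emulates the statistical situation the pipeline is built
for: a disease axis shared between species, an age axis only partially
shared, a human-specific sex confounder, and i.i.d. Gaussian noise.
Each latent axis is a unit-norm gene vector supported on a disjoint
block of ``planted_set_size`` genes; effect sizes are expressed as the
per-supported-gene signal amplitude in units of the noise standard
deviation, so ``beta_disease=2, noise_sd=1`` means every planted gene
shifts by two noise SDs per unit of disease dose. Concretely,

    human  x = beta_d * d * sqrt(s) * w_d
             + beta_a * z(age) * sqrt(s) * w_a
             + beta_s * sex * sqrt(s) * w_s + noise
    mouse  y = dose_effect * dose * sqrt(s) * w_d
             + age_effect * z(age) * sqrt(s) * w_a' + noise

with s the axis support size, z(.) standardized age, dose in {0, 1, 2}
and w_a' sharing a configurable fraction of its squared mass with the
human age axis. The bundle also carries an identity (optionally
relabeled) homolog map, the planted gene set with size-matched random
decoys, and the full ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .io import ExpressionStudy, GeneSetCollection, HomologMap
from .pca import PCAModel

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticBundle", "generate", "axis_alignment"]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_genes: int = 2000
    n_human_per_class: int = 30  # control and disease each
    n_mouse_per_group: int = 10  # per genotype x age cell
    mouse_ages: tuple[int, ...] = (2, 4, 8, 18)  # months
    beta_disease: float = 2.0  # per planted gene, units of noise sd
    beta_age: float = 1.0
    beta_sex: float = 0.5
    mouse_dose_effect: float = 1.0  # per unit dose (0/1/2)
    mouse_age_effect: float = 0.5
    age_axis_overlap: float = 0.5  # squared-mass fraction shared with human age axis
    noise_sd: float = 1.0
    planted_set_size: int = 50
    n_decoy_sets: int = 10
    distinct_mouse_ids: bool = False  # exercise non-identity homolog mapping
    seed: int = 17


@dataclass
class SyntheticTruth:
    """Ground truth recorded for recovery tests; axes are unit-norm."""

    gene_ids: pd.Index
    disease_axis: np.ndarray
    age_axis: np.ndarray
    mouse_age_axis: np.ndarray
    sex_axis: np.ndarray
    planted_genes: list[str]
    config: SimConfig

    def axes(self) -> dict[str, np.ndarray]:
        return {
            "disease": self.disease_axis,
            "age": self.age_axis,
            "mouse_age": self.mouse_age_axis,
            "sex": self.sex_axis,
        }


@dataclass
class SyntheticBundle:
    human: ExpressionStudy
    mouse: ExpressionStudy
    homolog_map: HomologMap
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _unit_axis(n_genes: int, support: np.ndarray) -> np.ndarray:
    w = np.zeros(n_genes)
    w[support] = 1.0 / np.sqrt(len(support))
    return w


def generate(config: SimConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate a paired human/mouse bundle with planted structure.

    Bit-reproducible for a fixed ``config.seed``; keyword overrides
    replace individual config fields.
    """
    cfg = config or SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    if cfg.n_genes < 50:
        raise ValueError("need at least 50 genes")
    if cfg.n_human_per_class < 2 or cfg.n_mouse_per_group < 2:
        raise ValueError("all group sizes must be >= 2")
    s = cfg.planted_set_size
    if 4 * s > cfg.n_genes:
        raise ValueError("planted_set_size too large for disjoint axis supports")
    if not 0.0 <= cfg.age_axis_overlap <= 1.0:
        raise ValueError("age_axis_overlap must be in [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = pd.Index([f"G{i:04d}" for i in range(G)], name="gene_id")

    perm = rng.permutation(G)
    sup_d, sup_a, sup_extra, sup_s = (
        perm[:s], perm[s: 2 * s], perm[2 * s: 3 * s], perm[3 * s: 4 * s]
    )
    w_d = _unit_axis(G, sup_d)
    w_a = _unit_axis(G, sup_a)
    w_extra = _unit_axis(G, sup_extra)
    w_s = _unit_axis(G, sup_s)
    f = cfg.age_axis_overlap
    w_ap = np.sqrt(f) * w_a + np.sqrt(1.0 - f) * w_extra  # unit: disjoint supports

    amp = np.sqrt(s)  # converts unit axis to per-gene amplitude 1 on support

    # ----- human cohort: balanced control/disease, random age and sex
    n_h = 2 * cfg.n_human_per_class
    d = np.repeat([0.0, 1.0], cfg.n_human_per_class)
    age_h = rng.integers(60, 91, n_h).astype(float)
    z_age_h = (age_h - age_h.mean()) / age_h.std(ddof=0)
    sex_h = rng.integers(0, 2, n_h).astype(float)
    Xh = (
        np.outer(w_d, cfg.beta_disease * amp * d)
        + np.outer(w_a, cfg.beta_age * amp * z_age_h)
        + np.outer(w_s, cfg.beta_sex * amp * sex_h)
        + rng.normal(0.0, cfg.noise_sd, (G, n_h))
    )
    human_ids = [f"H{i:03d}" for i in range(n_h)]
    human_meta = pd.DataFrame(
        {
            "age": age_h,
            "sex": np.where(sex_h > 0, "M", "F"),
            "disease_label": np.where(d > 0, "AD", "control"),
            "disease_code": d.astype(int),
        },
        index=pd.Index(human_ids, name="sample_id"),
    )
    human = ExpressionStudy(
        values=pd.DataFrame(Xh, index=gene_ids, columns=human_ids),
        metadata=human_meta,
        species="human",
    )

    # ----- mouse cohort: full genotype x age grid
    doses, ages = [], []
    for dose, month in product((0, 1, 2), cfg.mouse_ages):
        doses += [dose] * cfg.n_mouse_per_group
        ages += [month] * cfg.n_mouse_per_group
    dose_m = np.asarray(doses, float)
    age_m = np.asarray(ages, float)
    n_m = len(dose_m)
    z_age_m = (age_m - age_m.mean()) / age_m.std(ddof=0)
    Ym = (
        np.outer(w_d, cfg.mouse_dose_effect * amp * dose_m)
        + np.outer(w_ap, cfg.mouse_age_effect * amp * z_age_m)
        + rng.normal(0.0, cfg.noise_sd, (G, n_m))
    )
    if cfg.distinct_mouse_ids:
        mouse_gene_ids = pd.Index([f"m{g}" for g in gene_ids], name="gene_id")
    else:
        mouse_gene_ids = gene_ids
    mouse_ids = [f"M{i:03d}" for i in range(n_m)]
    label = np.select([dose_m == 0, dose_m == 1], ["WT", "HET"], default="HO")
    mouse_meta = pd.DataFrame(
        {
            "age": age_m,
            "sex": rng.choice(["M", "F"], n_m),
            "disease_label": label,
            "disease_code": dose_m.astype(int),
        },
        index=pd.Index(mouse_ids, name="sample_id"),
    )
    mouse = ExpressionStudy(
        values=pd.DataFrame(Ym, index=mouse_gene_ids, columns=mouse_ids),
        metadata=mouse_meta,
        species="mouse",
    )

    hmap = HomologMap.from_pairs(gene_ids, mouse_gene_ids)

    planted = sorted(gene_ids[sup_d])
    sets = {"planted_disease_axis": frozenset(planted)}
    descriptions = {"planted_disease_axis": "support of the shared disease axis"}
    for i in range(cfg.n_decoy_sets):
        name = f"decoy_{i + 1:02d}"
        members = rng.choice(G, size=s, replace=False)
        sets[name] = frozenset(gene_ids[members])
        descriptions[name] = "size-matched random decoy set"
    gene_sets = GeneSetCollection(sets=sets, descriptions=descriptions)

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        disease_axis=w_d,
        age_axis=w_a,
        mouse_age_axis=w_ap,
        sex_axis=w_s,
        planted_genes=planted,
        config=cfg,
    )
    return SyntheticBundle(
        human=human, mouse=mouse, homolog_map=hmap, gene_sets=gene_sets, truth=truth
    )


def axis_alignment(model: PCAModel, truth: SyntheticTruth) -> pd.DataFrame:
    """|cosine| between each retained component and each planted axis.

    The model may carry a subset of the truth's genes (e.g. after
    zero-variance drops); axes are restricted to the model's gene order
    before the cosine, and any model gene missing from the truth is an
    error.
    """
    missing = model.gene_order.difference(truth.gene_ids)
    if len(missing):
        raise ValueError(f"model genes absent from truth: {list(missing[:5])}")
    pos = truth.gene_ids.get_indexer(model.gene_order)
    rows = {}
    for name, axis in truth.axes().items():
        a = axis[pos]
        na = np.linalg.norm(a)
        if na == 0:
            rows[name] = np.zeros(model.n_components)
            continue
        cos = np.abs(model.loadings.T @ a) / (
            np.linalg.norm(model.loadings, axis=0) * na
        )
        rows[name] = cos
    return pd.DataFrame(rows, index=model.component_ids)
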