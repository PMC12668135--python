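"""Synthetic cohorts with known planted brain-behaviour structure.

The generator emulates what a multimodal imaging cohort looks like to the
prediction pipeline: family-clustered subjects, the eight standard
confounding variables, a set of feature-type blocks of two shapes
(vectorised connectivity matrices and region-wise scalar maps), and
psychometric targets built from a latent score planted in a configurable
subset of the blocks plus confound contamination and Gaussian noise.

Because the planted linear predictor is recorded in a manifest, every
downstream stage (feature-wise models, stacking, saturation inference) can
be tested against a known ground truth without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import CohortTable, FeatureBlock

import pandas as pd


@dataclass
class BlockSpec:
    """Shape description of one synthetic feature-type block."""

    name: str
    shape_kind: str = "region_map"   # or "connectivity_vector"
    modality_tag: str = "rest"
    n_features: int = 50             # ignored for connectivity_vector
    region_count: int | None = None  # required for connectivity_vector

    @property
    def width(self) -> int:
        if self.shape_kind == "connectivity_vector":
            r = self.region_count
            if r is None:
                raise ValueError(f"block {self.name!r} needs region_count")
            return r * (r - 1) // 2
        return self.n_features


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``signal_r2`` is the total fraction of target variance carried by the
    informative blocks (split according to ``effect_weights``),
    ``confound_r2`` the fraction contributed by confounds; the remainder is
    i.i.d. Gaussian noise.
    """

    n_subjects: int = 200
    blocks: tuple[BlockSpec, ...] = ()
    informative: tuple[str, ...] = ("fc_rest", "fc_task")
    effect_weights: tuple[float, ...] | None = None   # relative; None = equal
    signal_r2: float = 0.4
    confound_r2: float = 0.1
    latent_sharing: float = 0.5      # corr between block-expressed scores
    target_name: str = "score"
    sparsity: int = 5                # active columns/regions per planted block
    family_geom_p: float = 0.5       # truncated-geometric family sizes
    max_family_size: int = 5
    age_range: tuple[float, float] = (22.0, 36.0)
    heavy_tails: bool = False        # Student-t (df=5) noise instead of Gaussian
    folds_hint: int = 10             # intended outer CV folds, for sanity check

    def __post_init__(self) -> None:
        if not self.blocks:
            self.blocks = default_blocks()
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        unknown = set(self.informative) - set(names)
        if unknown:
            raise ValueError(f"informative blocks {sorted(unknown)} not defined")
        if not (0.0 <= self.signal_r2 <= 1.0 and 0.0 <= self.confound_r2 <= 1.0):
            raise ValueError("variance fractions must be in [0, 1]")
        if self.signal_r2 + self.confound_r2 > 1.0:
            raise ValueError("variance fractions sum above 1; refusing")
        if not 0.0 <= self.latent_sharing <= 0.95:
            raise ValueError("latent_sharing must be in [0, 0.95]")
        if self.n_subjects < 2 * self.folds_hint:
            raise ValueError(
                f"n_subjects={self.n_subjects} below 2x{self.folds_hint} folds")
        if self.effect_weights is not None and \
                len(self.effect_weights) != len(self.informative):
            raise ValueError("effect_weights must match informative blocks")


def default_blocks() -> tuple[BlockSpec, ...]:
    """Six blocks mimicking a small multimodal feature family."""
    return (
        BlockSpec("fc_rest", "connectivity_vector", "rest", region_count=20),
        BlockSpec("fc_task", "connectivity_vector", "task", region_count=20),
        BlockSpec("ec_rest", "connectivity_vector", "rest", region_count=20),
        BlockSpec("sc_count", "connectivity_vector", "diff", region_count=20),
        BlockSpec("morph_gmv", "region_map", "struct", n_features=50),
        BlockSpec("morph_ct", "region_map", "struct", n_features=50),
    )


@dataclass
class PlantedEffect:
    """Sparse linear combination through which a block expresses the latent."""

    block: str
    weight: float                    # contribution to target (std-units)
    columns: list[int]
    coefficients: list[float]
    center: float                    # latent standardisation: (B@beta - c)/s
    scale: float


@dataclass
class GroundTruthManifest:
    """Everything needed to reconstruct the planted target exactly."""

    seed: int
    target_name: str
    informative_types: list[str]
    effects: list[PlantedEffect]
    confound_contamination: float
    noise_variance: float
    confound_weights: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        """Planted signal part of the target, from the recorded combinations."""
        n = next(iter(blocks.values())).shape[0] if blocks else 0
        out = np.zeros(n)
        for eff in self.effects:
            b = blocks[eff.block]
            latent = b[:, eff.columns] @ np.asarray(eff.coefficients)
            out += eff.weight * (latent - eff.center) / eff.scale
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        d["effects"] = [PlantedEffect(**e) for e in d["effects"]]
        return cls(**d)


def export_manifest(manifest: GroundTruthManifest, path: str | Path) -> None:
    Path(path).write_text(manifest.to_json())


def load_manifest(path: str | Path) -> GroundTruthManifest:
    return GroundTruthManifest.from_json(Path(path).read_text())


def _family_sizes(rng: np.random.Generator, n: int, p: float,
                  max_size: int) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < n:
        s = min(int(rng.geometric(p)), max_size, n - total)
        sizes.append(s)
        total += s
    return sizes


def _confounds(rng: np.random.Generator, n: int,
               age_range: tuple[float, float]) -> pd.DataFrame:
    age = rng.uniform(*age_range, size=n)
    gender = rng.integers(1, 3, size=n).astype(float)
    # handedness: bimodal, mostly right-handed, clipped to the score range
    right = rng.random(n) < 0.9
    handedness = np.where(right,
                          rng.normal(75.0, 15.0, n),
                          rng.normal(-65.0, 20.0, n))
    handedness = np.clip(handedness, -100.0, 100.0)
    # ICV and brain size positively correlated, with a male>female shift
    male = gender == 2.0
    icv = rng.normal(1.5e6, 1.1e5, n) + np.where(male, 1.0e5, 0.0)
    icv = np.clip(icv, 1.0e6, None)
    brain_size = 0.75 * icv + rng.normal(0.0, 4.0e4, n)
    brain_size = np.clip(brain_size, 5.0e5, None)
    return pd.DataFrame({
        "age": age, "gender": gender, "handedness": handedness,
        "brain_size": brain_size, "icv": icv,
    })


def _planted_combination(rng: np.random.Generator, spec: BlockSpec,
                         sparsity: int) -> tuple[list[int], list[float]]:
    """Choose the sparse columns expressing the latent in one block.

    Connectivity blocks use a rank-1 pattern over region pairs (an outer
    product of a sparse region vector), so the elastic net at P >> N still
    faces a low-rank, solvable signal; region maps use plain sparse columns.
    """
    if spec.shape_kind == "connectivity_vector":
        r = spec.region_count
        regions = rng.choice(r, size=min(sparsity, r), replace=False)
        g = np.zeros(r)
        g[regions] = rng.normal(0.0, 1.0, size=len(regions))
        iu = np.triu_indices(r, k=1)
        pattern = np.outer(g, g)[iu]
        cols = np.nonzero(pattern)[0]
        return cols.tolist(), pattern[cols].tolist()
    p = spec.width
    cols = np.sort(rng.choice(p, size=min(sparsity, p), replace=False))
    coefs = rng.normal(0.0, 1.0, size=len(cols))
    return cols.tolist(), coefs.tolist()


def generate_cohort(spec: CohortSpec, seed: int
                    ) -> tuple[CohortTable, list[FeatureBlock],
                               GroundTruthManifest]:
    """Generate a cohort, its feature blocks and the ground-truth manifest.

    Deterministic under ``(spec, seed)``.  The target is

        y = sum_f w_f * z_f  +  c * confound_score  +  e

    where each ``z_f`` is a standardised sparse linear combination of block
    f's columns (recorded in the manifest), the confound score is a
    standardised combination of age, gender and ICV, and the coefficients
    are scaled so the planted variance fractions match ``spec``.
    """
    rng = np.random.default_rng(seed)

    # family structure
    sizes = _family_sizes(rng, spec.n_subjects, spec.family_geom_p,
                          spec.max_family_size)
    family_id = np.concatenate([
        np.full(s, f"fam{str(i).zfill(4)}") for i, s in enumerate(sizes)])
    subject_id = np.array([f"sub{str(i).zfill(4)}"
                           for i in range(spec.n_subjects)])

    conf = _confounds(rng, spec.n_subjects, spec.age_range)

    # feature blocks: pure standard-normal noise; informative ones then carry
    # the latent only through the recorded sparse combination of their columns
    matrices = {b.name: rng.normal(0.0, 1.0, size=(spec.n_subjects, b.width))
                for b in spec.blocks}

    weights = (np.ones(len(spec.informative))
               if spec.effect_weights is None
               else np.asarray(spec.effect_weights, dtype=float))
    if len(weights):
        weights = weights / np.sqrt(np.sum(weights ** 2))

    block_by_name = {b.name: b for b in spec.blocks}
    effects: list[PlantedEffect] = []
    # one subject-level latent trait, expressed in every informative block;
    # injecting it through the sparse pattern keeps each block-expressed
    # score an exact linear combination of that block's columns, so the
    # manifest reproduces the target without reference to the latent itself
    latent = rng.normal(0.0, 1.0, size=spec.n_subjects)
    s = spec.latent_sharing
    raw_scores = []
    for name, w_rel in zip(spec.informative, weights):
        cols, coefs = _planted_combination(rng, block_by_name[name],
                                           spec.sparsity)
        beta = np.asarray(coefs)
        if s > 0:
            gamma = np.sqrt(s / (1.0 - s)) / np.linalg.norm(beta)
            matrices[name][:, cols] += gamma * np.outer(latent, beta)
        raw_scores.append((name, w_rel, cols, coefs,
                           matrices[name][:, cols] @ beta))
    signal = np.zeros(spec.n_subjects)
    # normalise the summed block scores so the planted variance fraction is
    # signal_r2 regardless of sharing
    if raw_scores:
        zs = []
        for name, w_rel, cols, coefs, raw in raw_scores:
            center, scale = float(raw.mean()), float(raw.std())
            zs.append(w_rel * (raw - center) / scale)
        combined = np.sum(zs, axis=0)
        comb_sd = float(combined.std())
        for (name, w_rel, cols, coefs, raw), z in zip(raw_scores, zs):
            w = float(np.sqrt(spec.signal_r2) * w_rel / comb_sd)
            center, scale = float(raw.mean()), float(raw.std())
            effects.append(PlantedEffect(block=name, weight=w, columns=cols,
                                         coefficients=coefs, center=center,
                                         scale=scale))
        signal = np.sqrt(spec.signal_r2) * combined / comb_sd

    # confound contamination: standardised combination of age, gender, ICV
    cw = {"age": 0.6, "gender": 0.5, "icv": 0.4}
    raw_conf = sum(w * (conf[k] - conf[k].mean()) / conf[k].std(ddof=0)
                   for k, w in cw.items())
    raw_conf = np.asarray(raw_conf)
    sd = raw_conf.std()
    conf_score = raw_conf / sd if sd > 0 else raw_conf
    contamination = float(spec.confound_r2)

    noise_variance = max(1.0 - spec.signal_r2 - contamination, 0.0)
    if spec.heavy_tails:
        noise = rng.standard_t(df=5, size=spec.n_subjects) / np.sqrt(5 / 3)
    else:
        noise = rng.normal(0.0, 1.0, size=spec.n_subjects)
    target = (signal + np.sqrt(contamination) * conf_score
              + np.sqrt(noise_variance) * noise)

    table = pd.DataFrame({"subject_id": subject_id, "family_id": family_id})
    table = pd.concat([table, conf], axis=1)
    table[spec.target_name] = target
    cohort = CohortTable(table)

    blocks = [FeatureBlock(name=b.name, matrix=matrices[b.name],
                           modality_tag=b.modality_tag,
                           shape_kind=b.shape_kind,
                           region_count=b.region_count)
              for b in spec.blocks]

    manifest = GroundTruthManifest(
        seed=int(seed),
        target_name=spec.target_name,
        informative_types=list(spec.informative),
        effects=effects,
        confound_contamination=contamination,
        noise_variance=float(noise_variance),
        confound_weights=cw,
    )
    return cohort, blocks, manifest


@dataclass
class TimeseriesSet:
    """Per-subject region x time matrices plus the generating VAR(1) model."""

    series: dict[str, np.ndarray]
    tr: float
    ar_matrix: np.ndarray
    innovation_cov: np.ndarray

    @property
    def region_count(self) -> int:
        return self.ar_matrix.shape[0]


def generate_subject_timeseries(cohort: CohortTable, regions: int,
                                timepoints: int, ar_strength: float,
                                community_structure: list[list[int]] | None,
                                seed: int, *, within_corr: float = 0.5,
                                between_corr: float = 0.0,
                                tr: float = 0.8,
                                burn_in: int = 100) -> TimeseriesSet:
    """Simulate stationary VAR(1) region timeseries for every subject.

    ``x_t = A x_{t-1} + e_t`` with ``A = ar_strength * I`` and innovation
    correlation ``within_corr`` inside each community of
    ``community_structure`` (``between_corr`` across).  The generating A and
    covariance are recorded so tests can compare empirical estimates against
    them.
    """
    if timepoints < 2:
        raise ValueError("timepoints must be >= 2")
    A = float(ar_strength) * np.eye(regions)
    spectral_radius = np.max(np.abs(np.linalg.eigvals(A))) if regions else 0.0
    if spectral_radius >= 1.0:
        raise ValueError(
            f"unstable AR spectrum (spectral radius {spectral_radius:.3f} >= 1)")

    cov = np.full((regions, regions), between_corr, dtype=float)
    if community_structure:
        for comm in community_structure:
            for i in comm:
                for j in comm:
                    cov[i, j] = within_corr
    np.fill_diagonal(cov, 1.0)
    # tiny jitter guards the Cholesky against exactly singular block designs
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(regions))

    rng = np.random.default_rng(seed)
    series: dict[str, np.ndarray] = {}
    for sid in cohort.subject_ids:
        innov = rng.normal(size=(burn_in + timepoints, regions)) @ chol.T
        x = np.zeros((burn_in + timepoints, regions))
        x[0] = innov[0]
        a = float(ar_strength)
        for t in range(1, burn_in + timepoints):
            x[t] = a * x[t - 1] + innov[t]
        series[str(sid)] = x[burn_in:].T.copy()
    return TimeseriesSet(series=series, tr=tr, ar_matrix=A,
                         innovation_cov=cov)
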