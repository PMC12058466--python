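"""Seeded synthetic-data generators for spike-in and multi-batch TMT designs.

The intensity model is log-normal: on log2 scale,

    x_ij = mu_i + delta_i(cond(j)) + s_j [+ b_batch(j) + g_i,batch(j)] + eps_ij

with protein baselines mu_i ~ Uniform(20, 30), spike-in condition effects
delta = log2 of the known concentration ratio (0 for background proteins),
per-sample systematic shifts s_j ~ Normal(0, shift_sd^2) (the bias
normalization is supposed to remove), optional additive TMT-batch offsets
b_k ~ Normal(0, batch_sd^2) plus protein x batch interactions with half that
SD, and protein-specific noise eps ~ Normal(0, sigma_i^2), sigma_i ~
Uniform(noise_sd_range).  The generator returns the raw-scale dataset
(2**x), the spike-in truth table, and the full ground truth for
parameter-recovery tests.  Missingness can be layered on with a MAR
(uniform Bernoulli) plus MNAR (low-intensity logistic censoring) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ProteomicsDataset, SampleMetadata, Scale, SpikeInTruth

__all__ = [
    "SyntheticGroundTruth",
    "simulate_spikein",
    "simulate_tmt_batches",
    "inject_missingness",
    "SCENARIOS",
    "simulate_scenario",
]


@dataclass
class SyntheticGroundTruth:
    """Generator parameters retained for parameter-recovery tests."""

    mu: pd.Series  # per-protein log2 baseline
    sample_shifts: pd.Series  # per-sample systematic shift s_j
    noise_sd: pd.Series  # per-protein sigma_i
    spike_in: pd.Series  # bool per protein
    ratios: dict[str, float]  # condition -> concentration multiplier
    batch_offsets: pd.Series | None = None  # per-batch b_k
    missingness: dict = field(default_factory=dict)

    def expected_logfc(self, case: str, control: str) -> pd.Series:
        out = pd.Series(0.0, index=self.mu.index)
        out[self.spike_in] = np.log2(self.ratios[case] / self.ratios[control])
        return out


def _make_truth(
    protein_ids: pd.Index, spike: np.ndarray, ratios: dict[str, float]
) -> SpikeInTruth:
    label = pd.Series(
        np.where(spike, "spike_in", "background"), index=protein_ids, name="label"
    )
    conc = pd.DataFrame(np.nan, index=protein_ids, columns=list(ratios))
    for cond, ratio in ratios.items():
        conc.loc[spike, cond] = ratio
    return SpikeInTruth(label=label, concentration=conc)


def simulate_spikein(
    n_background: int = 2700,
    n_spikein: int = 300,
    groups: dict[str, int] | None = None,
    ratios: dict[str, float] | None = None,
    shift_sd: float = 0.5,
    noise_sd_range: tuple[float, float] = (0.1, 0.4),
    seed: int = 1,
) -> tuple[ProteomicsDataset, SpikeInTruth, SyntheticGroundTruth]:
    """Simulate a spike-in design: constant background proteome plus
    spike-in proteins at known per-condition concentrations.

    ``groups`` maps condition -> number of replicates (default two
    conditions of 4); ``ratios`` maps condition -> concentration multiplier
    of the spike-ins (default A:1, B:2, i.e. expected spike logFC of 1 for
    the B-A contrast).  Deterministic per ``seed``.
    """
    groups = groups or {"A": 4, "B": 4}
    ratios = ratios or {"A": 1.0, "B": 2.0}
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    if set(groups) != set(ratios):
        raise ValueError("groups and ratios must cover the same conditions")
    if n_background < 1 or n_spikein < 0 or any(n < 1 for n in groups.values()):
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    n = n_background + n_spikein
    width = len(str(n))
    protein_ids = pd.Index(
        [f"P{i:0{width}d}" for i in range(n)], name="protein"
    )
    spike = np.zeros(n, dtype=bool)
    spike[n_background:] = True

    mu = rng.uniform(20.0, 30.0, size=n)
    sigma = rng.uniform(*noise_sd_range, size=n)
    samples: list[SampleMetadata] = []
    for cond, size in groups.items():
        for r in range(size):
            samples.append(SampleMetadata(f"{cond}{r + 1}", cond))
    m = len(samples)
    shifts = rng.normal(0.0, shift_sd, size=m)
    X = np.empty((n, m))
    for j, s in enumerate(samples):
        delta = np.where(spike, np.log2(ratios[s.condition]), 0.0)
        X[:, j] = mu + delta + shifts[j] + rng.normal(0.0, sigma)
    sample_ids = [s.sample_id for s in samples]
    matrix = pd.DataFrame(2.0 ** X, index=protein_ids, columns=sample_ids)
    annotations = pd.DataFrame({"spike_in": spike}, index=protein_ids)
    ds = ProteomicsDataset(
        intensities=matrix, samples=samples, scale=Scale.RAW, annotations=annotations
    )
    truth = _make_truth(protein_ids, spike, ratios)
    gt = SyntheticGroundTruth(
        mu=pd.Series(mu, index=protein_ids),
        sample_shifts=pd.Series(shifts, index=sample_ids),
        noise_sd=pd.Series(sigma, index=protein_ids),
        spike_in=pd.Series(spike, index=protein_ids),
        ratios=dict(ratios),
    )
    return ds, truth, gt


def simulate_tmt_batches(
    n_background: int = 1200,
    n_spikein: int = 120,
    groups: dict[str, int] | None = None,
    ratios: dict[str, float] | None = None,
    shift_sd: float = 0.3,
    noise_sd_range: tuple[float, float] = (0.1, 0.4),
    n_batches: int = 3,
    batch_sd: float = 1.0,
    reference_per_batch: bool = True,
    seed: int = 1,
) -> tuple[ProteomicsDataset, SpikeInTruth, SyntheticGroundTruth]:
    """Simulate a multi-batch TMT spike-in design.

    Extends :func:`simulate_spikein` with additive per-batch offsets
    b_k ~ Normal(0, batch_sd^2) and protein x batch interactions
    Normal(0, (batch_sd/2)^2).  Samples are distributed round-robin over
    batches within each condition, so the design is (near-)balanced and
    batch is never confounded with condition.  With
    ``reference_per_batch=True`` each batch receives a pooled reference
    channel whose true content is the average over conditions.
    """
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    groups = groups or {"A": 6, "B": 6}
    ratios = ratios or {"A": 1.0, "B": 2.0}
    base_ds, truth, gt = simulate_spikein(
        n_background=n_background,
        n_spikein=n_spikein,
        groups=groups,
        ratios=ratios,
        shift_sd=shift_sd,
        noise_sd_range=noise_sd_range,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 10_000)
    n = base_ds.n_proteins
    batch_names = [f"B{k + 1}" for k in range(n_batches)]
    b = rng.normal(0.0, batch_sd, size=n_batches)
    inter = rng.normal(0.0, batch_sd / 2.0, size=(n, n_batches))
    # round-robin batch assignment within each condition
    assignment: dict[str, str] = {}
    for cond, cols in base_ds.condition_groups().items():
        for i, sample in enumerate(cols):
            assignment[sample] = batch_names[i % n_batches]

    X = np.log2(base_ds.intensities.to_numpy())
    samples: list[SampleMetadata] = []
    columns: list[np.ndarray] = []
    for j, s in enumerate(base_ds.samples):
        k = batch_names.index(assignment[s.sample_id])
        columns.append(X[:, j] + b[k] + inter[:, k])
        samples.append(
            SampleMetadata(s.sample_id, s.condition, batch=batch_names[k])
        )
    if reference_per_batch:
        spike = gt.spike_in.to_numpy()
        mean_delta = np.mean(
            [np.where(spike, np.log2(r), 0.0) for r in ratios.values()], axis=0
        )
        ref_content = gt.mu.to_numpy() + mean_delta
        sigma = gt.noise_sd.to_numpy()
        for k, bname in enumerate(batch_names):
            ref_shift = rng.normal(0.0, shift_sd)
            columns.append(
                ref_content + ref_shift + b[k] + inter[:, k]
                + rng.normal(0.0, sigma)
            )
            samples.append(
                SampleMetadata(
                    f"ref_{bname}", "reference", batch=bname, is_reference=True
                )
            )
    matrix = pd.DataFrame(
        2.0 ** np.column_stack(columns),
        index=base_ds.protein_ids,
        columns=[s.sample_id for s in samples],
    )
    ds = ProteomicsDataset(
        intensities=matrix,
        samples=samples,
        scale=Scale.RAW,
        annotations=base_ds.annotations,
    )
    gt.batch_offsets = pd.Series(b, index=batch_names)
    return ds, truth, gt


def inject_missingness(
    ds: ProteomicsDataset,
    mar_rate: float = 0.0,
    mnar_midpoint: float = 18.0,
    mnar_slope: float = 0.0,
    seed: int = 1,
) -> ProteomicsDataset:
    """Overlay MAR and MNAR missingness on a dataset.

    MAR: i.i.d. Bernoulli(``mar_rate``) mask.  MNAR: additional masking with
    probability logistic((mnar_midpoint - x_log2) * mnar_slope), i.e.
    low-abundance values are censored preferentially (``mnar_slope=0``
    disables the MNAR component since the probability is then a flat 0.5 —
    use slope > 0 for censoring, 0 together with ``mar_rate=0`` for no
    missingness at all).  Realized rates are not returned but derivable from
    the mask.  Deterministic per ``seed``.
    """
    if not 0.0 <= mar_rate <= 1.0:
        raise ValueError("mar_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    logx = ds.intensities.to_numpy(dtype=float)
    if ds.scale is Scale.RAW:
        with np.errstate(divide="ignore"):
            logx = np.log2(logx)
    mask = np.zeros(logx.shape, dtype=bool)
    if mar_rate > 0:
        mask |= rng.random(logx.shape) < mar_rate
    if mnar_slope > 0:
        p_mnar = 1.0 / (1.0 + np.exp(-(mnar_midpoint - logx) * mnar_slope))
        mask |= rng.random(logx.shape) < p_mnar
    out = ds.intensities.mask(pd.DataFrame(mask, index=ds.protein_ids,
                                           columns=ds.intensities.columns))
    return ds.with_matrix(out)


#: named study conditions used throughout the tests and the benchmark runs
SCENARIOS: dict[str, dict] = {
    # LFQ-style spike-in, 10% spike rate at ratio 2, moderate sample shifts
    "default": dict(
        kind="spikein",
        n_background=2700,
        n_spikein=300,
        groups={"A": 4, "B": 4},
        ratios={"A": 1.0, "B": 2.0},
        shift_sd=0.5,
        noise_sd_range=(0.1, 0.4),
    ),
    # three-batch TMT design with pooled reference channels
    "tmt3x": dict(
        kind="tmt",
        n_background=1200,
        n_spikein=120,
        groups={"A": 6, "B": 6},
        ratios={"A": 1.0, "B": 2.0},
        shift_sd=0.3,
        noise_sd_range=(0.1, 0.4),
        n_batches=3,
        batch_sd=1.0,
        reference_per_batch=True,
    ),
    # high spike rate concentrated in one condition: stresses global
    # shifting methods whose factors absorb the spike signal
    "asymmetric-spike": dict(
        kind="spikein",
        n_background=800,
        n_spikein=200,
        groups={"A": 4, "B": 4},
        ratios={"A": 1.0, "B": 4.0},
        shift_sd=0.3,
        noise_sd_range=(0.1, 0.4),
    ),
}


def simulate_scenario(
    name: str, seed: int = 1, **overrides
) -> tuple[ProteomicsDataset, SpikeInTruth, SyntheticGroundTruth]:
    """Run a named scenario from :data:`SCENARIOS` (overrides allowed)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}")
    cfg = {**SCENARIOS[name], **overrides}
    kind = cfg.pop("kind")
    if kind == "spikein":
        return simulate_spikein(seed=seed, **cfg)
    return simulate_tmt_batches(seed=seed, **cfg)
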