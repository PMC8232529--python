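"""Training protocols: grouped cross-validation, template refinement
(transfer), dataset ablation, and the desk-scale experiment suite.

The transfer protocol mirrors the template-model idea: a network trained
on a large primary domain with rough annotations is used as the weight
initializer ("template") when training on a small clean-labelled target
domain, and compared against training from scratch and against a template
trained on an unrelated (distractor) task.  The ablation protocol trains
templates on nested fractions of the primary dataset and measures how the
refined target performance depends on template-dataset size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import phantomgen
from .augment import AugmentConfig
from .evalmetrics import MetricRecord, aggregate, evaluate_case, paired_onetailed_test
from .imgio import derive_seed
from .phantomgen import DomainSpec, PhantomCase, generate_dataset, scaled_domain
from .preprocess import center_crop_pad, correct_bias, iqr_normalize, resample_isotropic
from .segmodel import UNetSegmenter, load_checkpoint, save_checkpoint


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of cases to cross-validation folds."""

    k: int
    assignment: dict  # case_id -> fold index
    grouped: bool

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(cid for cid, f in self.assignment.items() if f == fold)

    def train_cases(self, fold: int) -> list[str]:
        return sorted(cid for cid, f in self.assignment.items() if f != fold)


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters (optimizer is Adam, loss is soft Dice).

    The study-scale learning rate is 1e-5 over 100-epoch budgets; the desk
    presets (see :func:`desk_train_config`) use 3e-3 and short budgets
    because batch-1 training on tiny grids makes the study-scale rate
    impractically slow.
    """

    learning_rate: float = 1e-5
    epochs: int = 100
    base_features: int = 8
    encoder_levels: int = 4
    norm_groups: int = 8
    augment: Optional[AugmentConfig] = None
    seed: int = 0
    init: Optional[dict] = None  # template checkpoint for warm starts

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")


def desk_train_config(**overrides) -> TrainConfig:
    """Small-grid preset: base_features=4, Adam 3e-3, short epoch budgets."""
    defaults = dict(learning_rate=3e-3, epochs=16, base_features=4)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def _estimator(config: TrainConfig, seed_salt="") -> UNetSegmenter:
    return UNetSegmenter(
        base_features=config.base_features,
        encoder_levels=config.encoder_levels,
        norm_groups=config.norm_groups,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        augment=config.augment,
        init_weights=config.init,
        seed=derive_seed(config.seed, seed_salt) if seed_salt else config.seed,
    )


# ---------------------------------------------------------------------------
# Case preparation
# ---------------------------------------------------------------------------

def prepare_cases(
    cases: Sequence[PhantomCase],
    bias_correct: bool = False,
    target_spacing=None,
    crop_shape=None,
):
    """Normalize (and optionally bias-correct / resample / crop) phantom cases.

    Returns a list of (case_id, volume, clinical_mask, truth_mask) with the
    IQR normalization always applied (the network expects intensities on
    the normalized scale).  Phantoms generated at the network grid skip the
    geometric steps.
    """
    out = []
    for case in cases:
        vol = case.volume
        clin, truth = case.clinical_mask, case.truth_mask
        if bias_correct:
            vol = correct_bias(vol)
        if target_spacing is not None:
            vol = resample_isotropic(vol, target_spacing)
            clin = resample_isotropic(clin, target_spacing)
            truth = resample_isotropic(truth, target_spacing)
        vol, _ = iqr_normalize(vol)
        if crop_shape is not None:
            inplane, slices = int(crop_shape[0]), int(crop_shape[2])
            vol = center_crop_pad(vol, inplane, slices)
            clin = center_crop_pad(clin, inplane, slices)
            truth = center_crop_pad(truth, inplane, slices)
        out.append((case.case_id, vol, clin, truth))
    return out


def _train_tuples(prepared):
    """Training targets are the (possibly rough) clinical annotations."""
    return [(cid, vol, clin) for cid, vol, clin, _ in prepared]


# ---------------------------------------------------------------------------
# Folds and ablation
# ---------------------------------------------------------------------------

def make_folds(
    cases: Sequence[PhantomCase], k: int = 5, group_by_patient: bool = True, seed: int = 0
) -> FoldPlan:
    """Partition cases into k folds, keeping each patient's cases together.

    Patient groups are shuffled deterministically and dealt out cyclically,
    so fold sizes differ by at most one group.
    """
    groups: dict[str, list[str]] = {}
    for case in cases:
        key = case.patient_id if group_by_patient else case.case_id
        groups.setdefault(key, []).append(case.case_id)
    if len(groups) < k:
        raise ValueError(f"need at least {k} patient groups for {k} folds, have {len(groups)}")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    assignment = {}
    for i, key in enumerate(keys):
        for cid in groups[key]:
            assignment[cid] = i % k
    return FoldPlan(k=k, assignment=assignment, grouped=group_by_patient)


def truncate_training_set(
    train_cases: Sequence[PhantomCase], fraction: float, seed: int
) -> list[PhantomCase]:
    """Seed-deterministic random subset of round(fraction * n) cases (min 1).

    Subsets are nested across fractions: the permutation is drawn once from
    the seed and prefixes are taken, so subset(0.05) ⊆ subset(0.10).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cases = list(train_cases)
    if not cases:
        raise ValueError("empty training set")
    n_keep = max(1, int(np.floor(fraction * len(cases) + 0.5)))
    order = np.random.default_rng(seed).permutation(len(cases))
    return [cases[i] for i in order[:n_keep]]


# ---------------------------------------------------------------------------
# Training and cross-validation
# ---------------------------------------------------------------------------

def train_model(train_cases: Sequence[PhantomCase], config: TrainConfig, prepared=None):
    """Train one model; returns (checkpoint, per-epoch mean-loss history)."""
    if prepared is None:
        prepared = prepare_cases(train_cases)
    est = _estimator(config)
    est.fit(_train_tuples(prepared))
    return est.checkpoint(), est.history_


def crossval(
    cases: Sequence[PhantomCase],
    plan: FoldPlan,
    config: TrainConfig,
    model_tag: str = "cv",
    eval_against: str = "truth",
) -> tuple[dict, list[MetricRecord]]:
    """k-fold cross-validation: each case is evaluated exactly once, by the
    model trained without its fold.  Returns (per-fold checkpoints, records).
    """
    by_id = {c.case_id: c for c in cases}
    if set(plan.assignment) != set(by_id):
        raise ValueError("fold plan does not cover exactly the given cases")
    prepared = {p[0]: p for p in prepare_cases(cases)}
    checkpoints: dict[int, dict] = {}
    records: list[MetricRecord] = []
    for fold in range(plan.k):
        train_ids = plan.train_cases(fold)
        eval_ids = plan.fold_cases(fold)
        assert not set(train_ids) & set(eval_ids)
        fold_cfg = replace(config, seed=derive_seed(config.seed, "fold", fold))
        est = _estimator(fold_cfg)
        est.fit(_train_tuples([prepared[cid] for cid in train_ids]))
        checkpoints[fold] = est.checkpoint(
            meta={"fold": fold, "train_cases": train_ids}
        )
        for cid in eval_ids:
            _, vol, clin, truth = prepared[cid]
            ref = truth if eval_against == "truth" else clin
            pred = est.predict(vol)
            records.append(evaluate_case(cid, pred, ref, fold=fold, model_tag=model_tag))
    return checkpoints, records


def refine(
    template_checkpoint: dict,
    target_cases: Sequence[PhantomCase],
    plan: FoldPlan,
    config: TrainConfig,
    epochs: Optional[int] = None,
    model_tag: str = "refined",
    eval_against: str = "truth",
) -> tuple[dict, list[MetricRecord]]:
    """Cross-validated refinement of a pretrained template.

    ``epochs=0`` is the "before refining" condition: the raw template is
    evaluated on every fold without any weight update.
    """
    n_epochs = config.epochs if epochs is None else epochs
    if n_epochs == 0:
        prepared = {p[0]: p for p in prepare_cases(target_cases)}
        est = UNetSegmenter(
            base_features=template_checkpoint["spec"]["base_features"],
            encoder_levels=template_checkpoint["spec"]["encoder_levels"],
            norm_groups=template_checkpoint["spec"]["norm_groups"],
            init_weights=template_checkpoint,
        )
        records = []
        for cid, (_, vol, clin, truth) in sorted(prepared.items()):
            ref = truth if eval_against == "truth" else clin
            pred = est.predict(vol)
            fold = plan.assignment[cid]
            records.append(evaluate_case(cid, pred, ref, fold=fold, model_tag=model_tag))
        return {}, records
    cfg = replace(config, init=template_checkpoint, epochs=n_epochs)
    return crossval(target_cases, plan, cfg, model_tag=model_tag, eval_against=eval_against)


# ---------------------------------------------------------------------------
# Desk-scale experiment suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """Scale and protocol of one experiment-suite run.

    The defaults are the desk-scale conditions: 24x24x16 voxel phantoms,
    base_features=4 networks, a 16-case primary domain, a 12-case challenge
    domain split 6 train / 6 held-out, and an 8-case distractor domain.
    """

    grid_shape: tuple = (24, 24, 16)
    n_primary: int = 16
    n_primary_patients: int = 12
    n_challenge: int = 12
    n_challenge_train: int = 6
    n_ood: int = 8
    template_epochs: int = 24
    ood_epochs: int = 16
    finetune_epochs: int = 16
    ablation_fractions: tuple = (0.05, 0.25, 1.0)
    base_features: int = 4
    learning_rate: float = 3e-3
    augment: Optional[AugmentConfig] = None
    run_baselines: bool = False
    baseline_folds: int = 5
    seed: int = 0

    def desk_domains(self) -> dict[str, DomainSpec]:
        presets = phantomgen.load_domain_presets()
        # annotation roughness is scaled with the organ radius so that the
        # relative contour error matches the full-size primary preset
        return {
            "primaryA": scaled_domain(
                presets["primaryA"], self.grid_shape,
                annotation_roughness_mm=1.0, bias_strength=0.15,
            ),
            "challengeB": scaled_domain(
                presets["challengeB"], self.grid_shape, spacing_mm=(1.0, 1.0, 1.0),
                bias_strength=0.15,
            ),
            "oodD": scaled_domain(presets["oodD"], self.grid_shape, bias_strength=0.15),
        }


@dataclass
class SuiteResult:
    records: pd.DataFrame
    summary: dict
    checkpoints: dict


def _eval_on(est: UNetSegmenter, prepared, model_tag: str) -> list[MetricRecord]:
    records = []
    for cid, vol, clin, truth in prepared:
        pred = est.predict(vol)
        records.append(evaluate_case(cid, pred, truth, model_tag=model_tag))
    return records


def _fit_or_load(est: UNetSegmenter, tuples, out_dir, tag):
    """Train, or load a previously saved checkpoint when resuming."""
    if out_dir is not None:
        path = Path(out_dir) / f"{tag}.ckpt.npz"
        if path.exists():
            ckpt = load_checkpoint(path)
            est.init_weights = ckpt
            est._check_fitted()
            return est, ckpt
    est.fit(tuples)
    ckpt = est.checkpoint(meta={"tag": tag})
    if out_dir is not None:
        save_checkpoint(ckpt, Path(out_dir) / f"{tag}.ckpt.npz")
    return est, ckpt


def run_experiment_suite(config: SuiteConfig, out_dir=None) -> SuiteResult:
    """Run the transfer / ablation / out-of-domain comparison at desk scale.

    Per suite seed: pretrain templates on the full primary dataset, on
    nested ablated fractions of it, and on the distractor domain; then
    train target models on the challenge training split from scratch and
    from each template; evaluate all target models on the held-out
    challenge cases.  Optionally also runs per-domain baseline CV.

    Returns case-level records (tidy), a summary with mean Dice per model,
    the transfer ordering, the ablation Spearman correlation, and paired
    one-tailed test results.
    """
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    domains = config.desk_domains()
    seed = config.seed
    ds_a = generate_dataset(
        domains["primaryA"], config.n_primary, config.n_primary_patients,
        derive_seed(seed, "dsA"),
    )
    ds_b = generate_dataset(
        domains["challengeB"], config.n_challenge, config.n_challenge,
        derive_seed(seed, "dsB"),
    )
    ds_d = generate_dataset(
        domains["oodD"], config.n_ood, config.n_ood, derive_seed(seed, "dsD")
    )
    prep_a = prepare_cases(ds_a)
    prep_b = prepare_cases(ds_b)
    prep_d = prepare_cases(ds_d)
    b_train = prep_b[: config.n_challenge_train]
    b_eval = prep_b[config.n_challenge_train :]

    def cfg(epochs, salt, init=None):
        return replace(
            desk_train_config(
                base_features=config.base_features,
                learning_rate=config.learning_rate,
                epochs=epochs,
            ),
            augment=config.augment,
            seed=derive_seed(seed, salt),
            init=init,
        )

    checkpoints = {}
    records: list[MetricRecord] = []

    # -- templates: ablated primary + out-of-domain ------------------------
    for frac in sorted(config.ablation_fractions):
        subset = truncate_training_set(ds_a, frac, derive_seed(seed, "ablate"))
        tag = f"template_A{int(round(frac * 100)):03d}"
        sub_prep = [p for p in prep_a if p[0] in {c.case_id for c in subset}]
        est = _estimator(cfg(config.template_epochs, tag))
        est, ckpt = _fit_or_load(est, _train_tuples(sub_prep), out_dir, tag)
        checkpoints[tag] = ckpt
    est = _estimator(cfg(config.ood_epochs, "template_D"))
    est, ckpt = _fit_or_load(est, _train_tuples(prep_d), out_dir, "template_D")
    checkpoints["template_D"] = ckpt

    # -- target models on the challenge training split ---------------------
    full_tag = f"template_A{int(round(max(config.ablation_fractions) * 100)):03d}"
    target_inits = {"scratch": None, "ft_D": checkpoints["template_D"]}
    for frac in sorted(config.ablation_fractions):
        tag = f"template_A{int(round(frac * 100)):03d}"
        target_inits[f"ft_A{int(round(frac * 100)):03d}"] = checkpoints[tag]
    for tag, init in target_inits.items():
        est = _estimator(cfg(config.finetune_epochs, f"target_{tag}", init=init))
        est, ckpt = _fit_or_load(est, _train_tuples(b_train), out_dir, f"target_{tag}")
        checkpoints[f"target_{tag}"] = ckpt
        records += _eval_on(est, b_eval, model_tag=tag)

    # -- optional per-domain baseline CV ------------------------------------
    if config.run_baselines:
        for name, ds in (("A", ds_a), ("B", ds_b)):
            plan = make_folds(ds, k=config.baseline_folds, seed=derive_seed(seed, "folds", name))
            cv_ckpts, cv_records = crossval(
                ds, plan, cfg(config.template_epochs, f"baseline_{name}"),
                model_tag=f"baseline_{name}",
            )
            records += cv_records

    # -- summary -------------------------------------------------------------
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    mean_dice = {
        tag: float(df.loc[df.model_tag == tag, "dice_overall"].mean())
        for tag in sorted(df.model_tag.unique())
    }
    ft_full = f"ft_A{int(round(max(config.ablation_fractions) * 100)):03d}"
    ordering_ok = bool(
        mean_dice["scratch"] < mean_dice["ft_D"] < mean_dice[ft_full]
    )
    fracs = sorted(config.ablation_fractions)
    frac_means = [mean_dice[f"ft_A{int(round(f * 100)):03d}"] for f in fracs]
    rho = float(spearmanr(fracs, frac_means).statistic) if len(fracs) > 2 else float(
        np.sign(frac_means[-1] - frac_means[0])
    )
    per_case = df.pivot_table(index="case_id", columns="model_tag", values="dice_overall")
    tests = {}
    for tag in target_inits:
        if tag == "scratch":
            continue
        res = paired_onetailed_test(per_case[tag].values, per_case["scratch"].values)
        tests[f"{tag}_vs_scratch"] = {
            "t": res.t, "df": res.df, "p": res.p,
            "superior": res.superior, "degenerate": res.degenerate,
        }
    summary = {
        "seed": seed,
        "mean_dice": mean_dice,
        "transfer_ordering_ok": ordering_ok,
        "ablation_fractions": list(fracs),
        "ablation_mean_dice": frac_means,
        "ablation_spearman_rho": rho,
        "paired_tests": tests,
    }
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "results.csv", index=False)
        import json

        with open(Path(out_dir) / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return SuiteResult(records=df, summary=summary, checkpoints=checkpoints)
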