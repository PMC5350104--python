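"""End-to-end experiment orchestration.

``run_pipeline`` drives the whole modeling chain from one config: texture
synthesis -> surrogate population and targets -> LN baseline -> recurrent
network training -> probing -> population analyses -> JSON report.  All
randomness derives from the master seed; rerunning a config reproduces the
report bit-for-bit.  Intermediate artifacts are written under the output
directory with filenames tagged by a hash of the config section that
produced them, so stimuli generated under one config can never silently mix
with models trained under another.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from . import textures as tx
from .analysis import counterfactual_swap, dynamics_pca, form_motion_correlations, ridge_similarity
from .ln import LinearNonlinearModel
from .network import RecurrentFormAnalysis, RFAMResults
from .probing import selectivity_tables
from .surrogates import (
    class_mean_targets,
    consistency,
    make_population,
    simulate_population,
)
from .textures import CLASS_NAMES

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "generate_class_ensembles",
    "flatten_stimuli",
    "build_targets",
    "per_example_targets",
    "fit_rfampa",
    "tuning_curve_correlation",
]

#: Laminar composition of the recorded dataset that the surrogate population
#: emulates (area, layer) -> n_neurons.
FULL_POPULATION = {
    ("V1", "supra"): 32,
    ("V1", "gran"): 153,
    ("V1", "infra"): 71,
    ("V2", "supra"): 32,
    ("V2", "gran"): 34,
    ("V2", "infra"): 57,
}


@dataclass
class PipelineConfig:
    """One self-contained experiment specification."""

    master_seed: int = 0
    n_train: int = 200  # examples per class for training
    n_test: int = 1000  # fresh examples per class for generalization
    population: dict = field(default_factory=lambda: dict(FULL_POPULATION))
    n_repeats: int = 2
    n_hidden1: int = 30
    n_hidden2: int = 30
    n_epochs: int = 2_000_000
    learning_rate: float = 0.02
    momentum: float = 0.95
    ln_filters: int = 8
    probe_examples: int = 10_000
    swap_control: bool = True
    out_dir: str | None = None

    @classmethod
    def smoke(cls, out_dir: str | None = None) -> "PipelineConfig":
        """A tiny end-to-end configuration for fast checks."""
        return cls(
            n_train=20,
            n_test=50,
            population={("V1", "gran"): 5, ("V2", "supra"): 5},
            n_hidden1=8,
            n_hidden2=8,
            n_epochs=2000,
            learning_rate=0.05,
            ln_filters=3,
            probe_examples=20,
            swap_control=False,
            out_dir=out_dir,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["population"] = {f"{a}/{l}": n for (a, l), n in self.population.items()}
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["population"] = {
            tuple(k.split("/")): int(v) for k, v in d["population"].items()
        }
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(asdict(self).items()) if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


# ---------------------------------------------------------------------------
# reusable stages


def generate_class_ensembles(
    n_per_class: int, master_seed: int, stream: str
) -> dict[str, np.ndarray]:
    """One texture ensemble per MSCT class, seeded from the master seed."""
    return {
        c: tx.generate_ensemble(c, n_per_class, tx.stimulus_seed(master_seed, f"{stream}/{c}"))
        for c in CLASS_NAMES
    }


def flatten_stimuli(
    grids_by_class: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Blur, remap and flatten all classes; returns (stimuli, class labels)."""
    frames, labels = [], []
    for c, grids in grids_by_class.items():
        blurred = tx.blur_ensemble(grids)
        frames.append(blurred.reshape(grids.shape[0], -1))
        labels.extend([c] * grids.shape[0])
    return np.concatenate(frames), np.asarray(labels)


def build_targets(
    grids_by_class: dict[str, np.ndarray],
    population: dict[tuple[str, str], int],
    master_seed: int,
    n_repeats: int = 2,
):
    """Simulate the surrogate population and derive the V2pa training target.

    Returns ``(targets, responses, neurons, class_names)`` where ``targets``
    are the normalized class-mean time courses (n_classes, 5) of the V2
    supragranular population average and ``responses`` the full count array
    (n_neurons, n_classes, n_examples, n_repeats, 5).
    """
    neurons = make_population(population, seed=master_seed)
    responses, class_names = simulate_population(
        neurons, grids_by_class, n_repeats=n_repeats, seed=master_seed + 1
    )
    supra = [
        i for i, n in enumerate(neurons) if n.area == "V2" and n.layer == "supra"
    ]
    if not supra:
        raise ValueError("population contains no V2 supragranular neurons")
    targets = class_mean_targets(responses, subset=supra)
    return targets, responses, neurons, class_names


def per_example_targets(
    class_targets: np.ndarray, labels: np.ndarray, class_names: list[str]
) -> np.ndarray:
    """Expand class-mean target curves to one (5, 1) target per example."""
    lookup = {c: i for i, c in enumerate(class_names)}
    idx = np.array([lookup[c] for c in labels])
    return np.asarray(class_targets)[idx][:, :, None]


def fit_rfampa(
    stimuli: np.ndarray,
    labels: np.ndarray,
    class_targets: np.ndarray,
    class_names: list[str],
    n_hidden1: int = 30,
    n_hidden2: int = 30,
    n_epochs: int = 100_000,
    learning_rate: float = 0.01,
    seed: int = 0,
    **fit_kwargs,
) -> RFAMResults:
    """Train a single-output recurrent network on class-mean targets."""
    targets = per_example_targets(class_targets, labels, class_names)
    model = RecurrentFormAnalysis(stimuli, targets, n_hidden1, n_hidden2)
    return model.fit(
        n_epochs=n_epochs, learning_rate=learning_rate, seed=seed, **fit_kwargs
    )


def tuning_curve_correlation(
    results: RFAMResults,
    class_targets: np.ndarray,
    class_names: list[str],
    n_examples: int,
    master_seed: int,
    stream: str = "test",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pearson r between model and target 7-class tuning curves.

    The model curve is the output unit's response (mean over the five time
    steps) averaged over ``n_examples`` freshly generated textures per
    class; the target curve is the class-mean target averaged over bins.
    """
    grids = generate_class_ensembles(n_examples, master_seed, stream)
    model_curve = np.empty(len(class_names))
    for i, c in enumerate(class_names):
        blurred = tx.blur_ensemble(grids[c]).reshape(n_examples, -1)
        model_curve[i] = results.predict(blurred).mean()
    target_curve = np.asarray(class_targets).mean(axis=1)
    r = float(np.corrcoef(model_curve, target_curve)[0, 1])
    return r, model_curve, target_curve


# ---------------------------------------------------------------------------
# the full pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    t0 = time.time()
    cfg_hash = config.hash()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    stage = "stimuli"
    try:
        train_grids = generate_class_ensembles(
            config.n_train, config.master_seed, "train"
        )
        stimuli, labels = flatten_stimuli(train_grids)
        class_names = list(train_grids)

        stage = "surrogates"
        targets_tp, responses, neurons, class_names = build_targets(
            train_grids, config.population, config.master_seed, config.n_repeats
        )
        class_targets = targets_tp.values  # (n_classes, 5)
        supra = [
            i for i, n in enumerate(neurons) if n.area == "V2" and n.layer == "supra"
        ]
        v2pa_consistency = consistency(
            responses[supra].mean(axis=0), n_splits=1000, split_seed=config.master_seed
        )

        stage = "ln_baseline"
        # LN baseline fitted to the per-example population-average rate
        pa_rates = responses[supra].mean(axis=(0, 3, 4)).reshape(-1)  # (n_cls*n_ex,)
        ln_model = LinearNonlinearModel(stimuli, pa_rates)
        ln_res = ln_model.fit(n_filters=config.ln_filters)
        ln_train_r = ln_res.tuning_performance(stimuli, pa_rates, labels)
        test_grids = generate_class_ensembles(config.n_test, config.master_seed, "test")
        test_stimuli, test_labels = flatten_stimuli(test_grids)
        train_curve = np.array(
            [pa_rates[labels == c].mean() for c in np.unique(labels)]
        )
        ln_test_r = ln_res.tuning_performance(
            test_stimuli, train_curve, test_labels
        )

        stage = "rfam_training"
        results = fit_rfampa(
            stimuli,
            labels,
            class_targets,
            class_names,
            config.n_hidden1,
            config.n_hidden2,
            config.n_epochs,
            config.learning_rate,
            momentum=config.momentum,
            seed=config.master_seed,
        )
        if out_dir:
            gio.save_network(
                out_dir / f"rfampa_{cfg_hash}.h5",
                results.params,
                {"config_hash": cfg_hash, "seed": config.master_seed},
            )
        rfam_train_r, _, _ = tuning_curve_correlation(
            results, class_targets, class_names, min(config.n_train, config.n_test),
            config.master_seed, stream="train",
        )
        rfam_test_r, model_curve, target_curve = tuning_curve_correlation(
            results, class_targets, class_names, config.n_test,
            config.master_seed, stream="test",
        )

        stage = "probing"
        indices = selectivity_tables(
            results, ("H1", "H2"),
            n_examples=config.probe_examples, seed=config.master_seed,
        )
        if out_dir:
            for layer, df in indices.items():
                df.to_csv(out_dir / f"indices_{layer}_{cfg_hash}.csv")

        stage = "analysis"
        fm = {
            layer: form_motion_correlations(indices[layer]) for layer in indices
        }
        # temporal dynamics: hidden units + surrogate neurons on one basis
        h1 = results.hidden_responses(stimuli, "H1")
        h2 = results.hidden_responses(stimuli, "H2")
        unit_courses = np.concatenate(
            [h1.mean(axis=0).T, h2.mean(axis=0).T]
        )  # (n1+n2, 5)
        neuron_courses = responses.mean(axis=(1, 2, 3))  # (n_neurons, 5)
        all_courses = np.concatenate([unit_courses, neuron_courses])
        shifts = np.r_[
            np.zeros(unit_courses.shape[0], dtype=int),
            np.ones(neuron_courses.shape[0], dtype=int),
        ]
        groups = (
            ["H1"] * config.n_hidden1
            + ["H2"] * config.n_hidden2
            + [f"{n.area}/{n.layer}" for n in neurons]
        )
        embedding = dynamics_pca(all_courses, shifts, group_labels=np.array(groups))

        # ridge similarity between unit sets and surrogate areas
        cond_mean = responses.mean(axis=(2, 3))  # (n_neurons, n_classes, 5)
        h1_cond = np.stack(
            [h1[labels == c].mean(axis=0) for c in class_names]
        ).reshape(len(class_names) * 5, -1)
        h2_cond = np.stack(
            [h2[labels == c].mean(axis=0) for c in class_names]
        ).reshape(len(class_names) * 5, -1)
        v1_idx = [i for i, n in enumerate(neurons) if n.area == "V1"]
        v2_idx = [i for i, n in enumerate(neurons) if n.area == "V2"]
        similarities = {}
        for src_name, src in (("H1", h1_cond), ("H2", h2_cond)):
            for tgt_name, tgt_idx in (("V1", v1_idx), ("V2", v2_idx)):
                if not tgt_idx:
                    continue
                tgt = cond_mean[tgt_idx].reshape(len(tgt_idx), -1).T
                sim = ridge_similarity(src, tgt, pair=f"{tgt_name}~{src_name}")
                similarities[f"{tgt_name}~{src_name}"] = sim.r_mean

        swap_report = None
        if config.swap_control:
            stage = "swap_control"
            swapped = counterfactual_swap(targets_tp, class_names)
            swap_results = fit_rfampa(
                stimuli,
                labels,
                swapped.values,
                class_names,
                config.n_hidden1,
                config.n_hidden2,
                config.n_epochs,
                config.learning_rate,
                momentum=config.momentum,
                seed=config.master_seed,
            )
            swap_indices = selectivity_tables(
                swap_results, ("H1", "H2"),
                n_examples=config.probe_examples, seed=config.master_seed,
            )
            swap_fm = {
                layer: form_motion_correlations(df)
                for layer, df in swap_indices.items()
            }
            swap_report = {
                layer: {
                    "max_abs_r": float(np.nanmax(np.abs(df.to_numpy(dtype=float))))
                }
                for layer, df in swap_fm.items()
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "config_hash": cfg_hash,
        "master_seed": config.master_seed,
        "elapsed_s": round(time.time() - t0, 2),
        "v2pa_consistency": round(v2pa_consistency, 4),
        "ln": {"train_r": round(ln_train_r, 4), "test_r": round(ln_test_r, 4)},
        "rfampa": {
            "n_params": results.params.n_params,
            "train_r": round(rfam_train_r, 4),
            "test_r": round(rfam_test_r, 4),
            "model_tuning_curve": [round(float(v), 5) for v in model_curve],
            "target_tuning_curve": [round(float(v), 5) for v in target_curve],
        },
        "form_motion_correlations": {
            layer: {
                col: {row: round(float(df.loc[row, col]), 4) for row in df.index}
                for col in df.columns
            }
            for layer, df in fm.items()
        },
        "pca": {
            "variance_explained_first_two": round(
                float(embedding.variance_explained[:2].sum()), 4
            )
        },
        "similarity": {k: round(v, 4) for k, v in similarities.items()},
        "swap_control": swap_report,
    }
    if out_dir:
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2)
    return report
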