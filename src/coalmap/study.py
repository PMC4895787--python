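"""Replication of the simulation-based validation study.

One *condition* is a (hybridization frequency gamma, trait architecture)
pair; one *replicate* is simulate alignment -> infer Four-Gamete-Test
breakpoints -> draw causal SNPs and trait -> score every SNP with both
Coal-Map and the EIGENSTRAT-style baseline.  Per condition the per-SNP
p-values of all replicates are pooled into one ROC per method, and the
two AUROCs are compared with the DeLong test; Benjamini-Hochberg runs
across the conditions of one study (the rows of the final table form a
single test family).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .alignment import HaploidAlignment
from .assoc import eigenstrat_scores, score_alignment
from .coalescent import SimParams, simulate_alignment
from .evaluate import bh_correct, delong_test, roc_and_auroc
from .partition import infer_breakpoints, PartitionSet
from .traits import InsufficientEligibleSNPsError, simulate_trait_realization

__all__ = ["Condition", "StudyConfig", "run_replicate", "run_condition",
           "run_study", "summarize_study", "DEFAULT_GRID"]

_MAX_RETRIES = 5  # fresh-seed retries for a failed replicate


@dataclass(frozen=True)
class Condition:
    """One cell of the study grid."""

    gamma: float
    architecture: str  # "single" | "two" | "all"
    pi: float = 0.9
    replicates: int = 20
    sim: SimParams = field(default_factory=SimParams)
    n_causal: int = 20
    maf_lo: float = 0.1
    maf_hi: float = 0.3

    @property
    def label(self) -> str:
        return f"gamma{self.gamma:g}_{self.architecture}"


@dataclass
class StudyConfig:
    conditions: list[Condition]
    seed: int = 1
    rule: str = "minp"
    n_global_pcs: int = 5
    n_local_pcs: int = 5
    n_baseline_pcs: int = 10
    use_truth_breakpoints: bool = False
    out_dir: Path | None = None


def default_grid(
    gammas=(0.5, 0.25, 0.1, 0.01),
    architectures=("single", "two", "all"),
    replicates: int = 20,
    sim: SimParams | None = None,
    pi: float = 0.9,
) -> list[Condition]:
    sim = sim or SimParams()
    return [
        Condition(gamma=g, architecture=a, pi=pi, replicates=replicates, sim=sim)
        for a in architectures
        for g in gammas
    ]


DEFAULT_GRID = default_grid()


def _replicate_seed(root_seed: int, label: str, rep: int, attempt: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    tag = f"{root_seed}:{label}:{rep}:{attempt}".encode()
    return zlib.crc32(tag) % (2**31)


def run_replicate(
    cond: Condition,
    seed: int,
    rule: str = "minp",
    n_global_pcs: int = 5,
    n_local_pcs: int = 5,
    n_baseline_pcs: int = 10,
    use_truth_breakpoints: bool = False,
) -> dict:
    """Simulate and score one replicate dataset.

    Returns the alignment, partition set, trait truth, the Coal-Map
    result table (with the baseline p-values in column
    ``p_eigenstrat``) and the causal-label vector.
    """
    params = replace(cond.sim, gamma=cond.gamma, seed=seed)
    aln = simulate_alignment(params)
    if use_truth_breakpoints:
        parts = PartitionSet.from_ranges(aln.locus_bounds)
    else:
        parts = infer_breakpoints(aln)
    trait_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    )
    trait = simulate_trait_realization(
        aln,
        cond.architecture,
        pi=cond.pi,
        count=cond.n_causal,
        maf_lo=cond.maf_lo,
        maf_hi=cond.maf_hi,
        rng=trait_rng,
    )
    results = score_alignment(
        aln, parts, trait.y, rule=rule,
        n_global_pcs=n_global_pcs, n_local_pcs=n_local_pcs,
    )
    results["p_eigenstrat"] = eigenstrat_scores(aln, trait.y, n_baseline_pcs)
    labels = np.zeros(aln.n_sites, dtype=bool)
    labels[trait.delta] = True
    results["causal"] = labels
    # min-P dominance must hold replicate by replicate
    assert (
        results["p_value"] <= np.minimum(results["p_global"], results["p_glocal"]) + 1e-15
    ).all() or rule != "minp"
    return {
        "alignment": aln,
        "partitions": parts,
        "trait": trait,
        "results": results,
        "seed": seed,
    }


def _write_replicate(rep_dir: Path, rep: dict) -> None:
    rep_dir.mkdir(parents=True, exist_ok=True)
    aln = rep["alignment"]
    cio.write_alignment_tsv(aln, rep_dir / "alignment.tsv")
    cio.write_breakpoints(rep["partitions"], rep_dir / "breakpoints.tsv")
    cio.write_phenotype(aln.sample_ids, rep["trait"].y, rep_dir / "phenotype.tsv")
    cio.write_causal(aln, rep["trait"].delta, rep_dir / "causal.tsv")
    with (rep_dir / "assoc.tsv").open("w") as fh:
        fh.write("# coalmap assoc v1\n")
        rep["results"].to_csv(fh, sep="\t", index=False)


def run_condition(
    cond: Condition,
    root_seed: int,
    rule: str = "minp",
    n_global_pcs: int = 5,
    n_local_pcs: int = 5,
    n_baseline_pcs: int = 10,
    use_truth_breakpoints: bool = False,
    out_dir: Path | None = None,
    fpr_target: float = 0.05,
    keep_replicates: bool = False,
) -> dict:
    """Run all replicates of one condition and evaluate the pooled ROC."""
    pooled_cm: list[np.ndarray] = []
    pooled_es: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    per_rep_rows = []
    replicates = []
    skipped = 0
    for rep in range(cond.replicates):
        result = None
        for attempt in range(_MAX_RETRIES):
            seed = _replicate_seed(root_seed, cond.label, rep, attempt)
            try:
                result = run_replicate(
                    cond, seed, rule=rule,
                    n_global_pcs=n_global_pcs, n_local_pcs=n_local_pcs,
                    n_baseline_pcs=n_baseline_pcs,
                    use_truth_breakpoints=use_truth_breakpoints,
                )
                break
            except (InsufficientEligibleSNPsError, RuntimeError):
                continue
        if result is None:
            skipped += 1
            continue
        res = result["results"]
        pooled_cm.append(res["p_value"].to_numpy())
        pooled_es.append(res["p_eigenstrat"].to_numpy())
        pooled_labels.append(res["causal"].to_numpy())
        per_rep_rows.append(
            {
                "replicate": rep,
                "seed": result["seed"],
                "n_sites": result["alignment"].n_sites,
                "n_partitions": result["partitions"].n_partitions,
                "auroc_coalmap": roc_and_auroc(
                    res["p_value"].to_numpy(), res["causal"].to_numpy()
                ).auroc,
                "auroc_eigenstrat": roc_and_auroc(
                    res["p_eigenstrat"].to_numpy(), res["causal"].to_numpy()
                ).auroc,
            }
        )
        if out_dir is not None:
            _write_replicate(Path(out_dir) / cond.label / f"rep{rep:02d}", result)
        if keep_replicates:
            replicates.append(result)

    p_cm = np.concatenate(pooled_cm)
    p_es = np.concatenate(pooled_es)
    labels = np.concatenate(pooled_labels)
    roc_cm = roc_and_auroc(p_cm, labels, fpr_target)
    roc_es = roc_and_auroc(p_es, labels, fpr_target)
    auc_a, auc_b, z, p = delong_test(p_cm, p_es, labels)
    return {
        "condition": cond,
        "label": cond.label,
        "roc_coalmap": roc_cm,
        "roc_eigenstrat": roc_es,
        "delong_z": z,
        "delong_p": p,
        "pooled": {"p_coalmap": p_cm, "p_eigenstrat": p_es, "labels": labels},
        "per_replicate": pd.DataFrame(per_rep_rows),
        "skipped": skipped,
        "replicates": replicates,
    }


def summarize_study(condition_results: list[dict], alpha: float = 0.05) -> pd.DataFrame:
    """Table-style study summary with BH q-values across the conditions."""
    if not condition_results:
        raise ValueError("no condition results to summarize")
    rows = []
    for r in condition_results:
        cond = r["condition"]
        rows.append(
            {
                "condition": r["label"],
                "gamma": cond.gamma,
                "architecture": cond.architecture,
                "pi": cond.pi,
                "replicates": cond.replicates - r["skipped"],
                "skipped": r["skipped"],
                "auroc_coalmap": r["roc_coalmap"].auroc,
                "auroc_eigenstrat": r["roc_eigenstrat"].auroc,
                "tpr05_coalmap": r["roc_coalmap"].tpr_at_fpr,
                "tpr05_eigenstrat": r["roc_eigenstrat"].tpr_at_fpr,
                "delong_z": r["delong_z"],
                "delong_p": r["delong_p"],
            }
        )
    df = pd.DataFrame(rows)
    qvals, reject = bh_correct(df["delong_p"].to_numpy(), alpha=alpha)
    df["q_value"] = qvals
    df["significant"] = reject
    return df


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Run every condition of a study and return (summary, raw results)."""
    results = []
    for cond in config.conditions:
        results.append(
            run_condition(
                cond,
                config.seed,
                rule=config.rule,
                n_global_pcs=config.n_global_pcs,
                n_local_pcs=config.n_local_pcs,
                n_baseline_pcs=config.n_baseline_pcs,
                use_truth_breakpoints=config.use_truth_breakpoints,
                out_dir=config.out_dir,
            )
        )
    summary = summarize_study(results)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "summary.tsv").open("w") as fh:
            fh.write("# coalmap summary v1\n")
            summary.to_csv(fh, sep="\t", index=False)
    return summary, results
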