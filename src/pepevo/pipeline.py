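"""One full in-silico evolution round, leave-out validation, candidate design.

A round chains the stages end to end: fit the Potts model to the family
alignment, generate a novel scaffold-constrained pool by Metropolis MC,
predict each novel sequence's Ki with the random-forest regressor, keep the
sequences predicted strictly below the configured percentile of the
reference distribution, and distill the surviving pool into a position
frequency logo and a short list of consensus-style design candidates.
Iterative campaigns (augmenting the family with newly measured variants and
re-running) are just repeated calls on a grown record table — there is no
special second-round code path.

A single master seed derives every stage seed, so a round is reproducible
bit for bit; each round writes a JSON-able manifest with counts, thresholds,
Meff and acceptance statistics, the only sanity scale available when
comparing against published campaign numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .affinity_model import (FeatureSpec, KiForest, RegressorConfig,
                             filter_by_threshold, percentile_threshold)
from .mc_sampler import SamplePool, SamplerConfig, sample_sequences
from .plmdca import PottsPseudolikelihood
from .seq_core import (MSA, AffinityRecord, Alphabet, FrequencyMatrix,
                       Scaffold, frequency_matrix, information_content)

logger = logging.getLogger("pepevo")


def _stage_seed(master: int, offset: int) -> int:
    return (master * 7919 + offset) % 2 ** 31


@dataclass
class RoundConfig:
    """Everything one generation round needs; ``seed`` is the master seed
    from which all stage seeds are derived."""

    seed: int = 0
    percentile: float = 50.0
    percentile_reference: str = "generated"   # or "training"
    lambda_h: float = 0.01
    lambda_J: float = 0.01
    reweight: bool = False
    identity_threshold: float = 0.8
    max_iter: int = 500
    tol: float = 1e-5
    sampler: SamplerConfig = dc_field(default_factory=SamplerConfig)
    regressor: RegressorConfig = dc_field(default_factory=RegressorConfig)
    feature_spec: FeatureSpec = dc_field(default_factory=FeatureSpec)
    logo_pseudocount: float = 0.0
    runner_up_fraction: float = 0.5
    max_candidates: int = 8

    def __post_init__(self) -> None:
        if self.percentile_reference not in ("generated", "training"):
            raise ValueError("percentile_reference must be 'generated' or 'training'")
        if not 0 < self.runner_up_fraction <= 1:
            raise ValueError("runner_up_fraction must be in (0, 1]")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")

    def stage_seeds(self) -> dict[str, int]:
        return {"sampler": _stage_seed(self.seed, 1),
                "regressor": _stage_seed(self.seed, 2)}

    def to_dict(self) -> dict:
        return {"seed": self.seed, "percentile": self.percentile,
                "percentile_reference": self.percentile_reference,
                "lambda_h": self.lambda_h, "lambda_J": self.lambda_J,
                "reweight": self.reweight,
                "identity_threshold": self.identity_threshold,
                "max_iter": self.max_iter, "tol": self.tol,
                "sampler": self.sampler.to_dict(),
                "regressor": self.regressor.to_dict(),
                "use_onehot": self.feature_spec.use_onehot,
                "descriptors": list(self.feature_spec.descriptors),
                "logo_pseudocount": self.logo_pseudocount,
                "runner_up_fraction": self.runner_up_fraction,
                "max_candidates": self.max_candidates}


@dataclass
class GenerationResult:
    """Bundle of one round's artifacts (pool, predictions, selection, logo)."""

    pool: SamplePool
    predictions: np.ndarray            # molar, parallel to pool.novel
    threshold: float                   # molar
    selected: list[tuple[str, float, float]]  # (sequence, score, predicted Ki)
    logo: FrequencyMatrix | None
    ic_bits: np.ndarray | None
    candidates: list[str]
    provenance: dict

    def manifest(self) -> dict:
        man = dict(self.provenance)
        man.update({
            "n_recorded": self.pool.total_recorded,
            "n_unique": len(self.pool.samples),
            "n_novel": len(self.pool.novel),
            "acceptance_rate": self.pool.acceptance_rate,
            "threshold_molar": self.threshold,
            "n_selected": len(self.selected),
            "selected": [[s, round(sc, 12), ki] for s, sc, ki in self.selected],
            "candidates": self.candidates,
        })
        return man

    def hash(self) -> str:
        payload = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def save(self, outdir: str | Path) -> None:
        from .io import write_frequency_tsv, write_logo_json, write_sequences_fasta
        from .mc_sampler import export_pool_tsv
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        export_pool_tsv(self.pool, outdir / "pool.tsv")
        pd.DataFrame(self.selected,
                     columns=["sequence", "score", "predicted_ki_molar"]
                     ).to_csv(outdir / "selected.tsv", sep="\t", index=False)
        if self.logo is not None:
            write_frequency_tsv(self.logo, outdir / "logo.tsv")
            scaffold = Scaffold.from_dict(self.provenance["scaffold"])
            write_logo_json(self.logo, scaffold, outdir / "logo.json")
        if self.candidates:
            write_sequences_fasta(
                [f"candidate{k + 1}" for k in range(len(self.candidates))],
                self.candidates, outdir / "candidates.fasta")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True))


@dataclass
class RecoveryReport:
    """Outcome of a leave-out experiment: which held-out binders came back."""

    held_out_ids: list[str]
    regenerated: list[str]             # held-out ids found in the selected pool
    pool_size: int
    selected_size: int
    score_rank: dict[str, int | None]  # 1-based rank in novel pool by score
    ki_rank: dict[str, int | None]     # 1-based rank by predicted Ki
    result: GenerationResult

    @property
    def all_recovered(self) -> bool:
        return set(self.regenerated) == set(self.held_out_ids)


def run_generation_round(records: list[AffinityRecord], scaffold: Scaffold,
                         config: RoundConfig | None = None,
                         alphabet: Alphabet | None = None) -> GenerationResult:
    """Execute one full round; deterministic given (records, config).

    An empty novel pool or empty selection produces a result with empty
    fields and a logged warning rather than an exception, so campaign loops
    can carry on.
    """
    config = config or RoundConfig()
    alphabet = alphabet or Alphabet()
    if len(records) < 5:
        raise ValueError("need at least 5 affinity records")
    seeds = config.stage_seeds()
    training = [r.sequence for r in records]
    msa = MSA.from_sequences([r.id for r in records], training, scaffold,
                             alphabet)

    dca = PottsPseudolikelihood(
        msa, lambda_h=config.lambda_h, lambda_J=config.lambda_J,
        reweight=config.reweight,
        identity_threshold=config.identity_threshold).fit(
            max_iter=config.max_iter, tol=config.tol)

    sampler_cfg = SamplerConfig(**{**config.sampler.to_dict(),
                                   "seed": seeds["sampler"]})
    pool = sample_sequences(dca.model, scaffold, sampler_cfg,
                            exclude=set(training), init_sequences=training)

    provenance = {"config": config.to_dict(), "stage_seeds": seeds,
                  "scaffold": scaffold.to_dict(),
                  "n_training": len(records),
                  "meff": dca.model.meta["meff"],
                  "dca_iterations": dca.n_iter,
                  "dca_converged": dca.converged,
                  "model_digest": dca.model.digest()}

    novel_seqs = [s.sequence for s in pool.novel]
    if not novel_seqs:
        logger.warning("round produced no novel sequences")
        return GenerationResult(pool=pool, predictions=np.array([]),
                                threshold=float("nan"), selected=[],
                                logo=None, ic_bits=None, candidates=[],
                                provenance=provenance)

    reg_cfg = RegressorConfig(**{**config.regressor.to_dict(),
                                 "seed": seeds["regressor"]})
    rf = KiForest(records, scaffold, spec=config.feature_spec,
                  config=reg_cfg, alphabet=alphabet).fit()
    predictions = rf.predict_ki(novel_seqs)
    provenance["rf_cv_rmse"] = rf.report.cv_rmse
    provenance["rf_train_rmse"] = rf.report.train_rmse

    if config.percentile_reference == "generated":
        reference = predictions
    else:
        reference = np.array([r.ki for r in records])
    threshold = percentile_threshold(reference, config.percentile)

    score_by_seq = {s.sequence: s.score for s in pool.novel}
    kept, fraction = filter_by_threshold(novel_seqs, predictions, threshold)
    selected = [(seq, score_by_seq[seq], ki) for seq, ki in kept]
    provenance["selected_fraction"] = fraction

    logo = None
    ic = None
    candidates: list[str] = []
    if selected:
        sel_msa = MSA.from_sequences(
            [f"sel{k + 1:05d}" for k in range(len(selected))],
            [s for s, _, _ in selected], scaffold, alphabet)
        logo = frequency_matrix(sel_msa, pseudocount=config.logo_pseudocount)
        ic = information_content(logo)
        candidates = design_candidates(logo, scaffold,
                                       runner_up_fraction=config.runner_up_fraction,
                                       max_candidates=config.max_candidates)
    else:
        logger.warning("no sequence predicted below the threshold; "
                       "selection is empty")

    return GenerationResult(pool=pool, predictions=predictions,
                            threshold=threshold, selected=selected,
                            logo=logo, ic_bits=ic, candidates=candidates,
                            provenance=provenance)


def suggest_holdouts(records: list[AffinityRecord], max_fraction: float = 0.05,
                     exclude_best: bool = True) -> list[str]:
    """Pick leave-out candidates: potent but not the most potent.

    Eligible records have Ki strictly below the family median; the single
    most potent record is excluded (the validation should not hand the
    pipeline its best answer, nor its hardest). Of the eligible ones the most
    potent are returned, capped at floor(max_fraction * n) — mirroring the
    published choice of mid-family binders at under 5% of the data set.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    if not 0 < max_fraction <= 0.5:
        raise ValueError("max_fraction must be in (0, 0.5]")
    kis = np.array([r.ki for r in records])
    median = float(np.median(kis))
    best_id = records[int(np.argmin(kis))].id
    eligible = [r for r in records if r.ki < median
                and (not exclude_best or r.id != best_id)]
    eligible.sort(key=lambda r: (r.ki, r.id))
    cap = int(np.floor(max_fraction * len(records)))
    return [r.id for r in eligible[:cap]]


def leave_out_experiment(records: list[AffinityRecord], scaffold: Scaffold,
                         held_out_ids: list[str],
                         config: RoundConfig | None = None,
                         alphabet: Alphabet | None = None) -> RecoveryReport:
    """Remove the named records, run a round, and check regeneration.

    A held-out sequence counts as regenerated when it appears in the selected
    pool. Ranks (1 = best) are reported within the full novel pool, by Potts
    score (descending) and by predicted Ki (ascending); ``None`` means the
    sequence was never generated at all. A held-out sequence identical to a
    remaining training sequence is flagged: it is excluded from sampling as
    training and the experiment is degenerate for it.
    """
    by_id = {r.id: r for r in records}
    unknown = [h for h in held_out_ids if h not in by_id]
    if unknown:
        raise ValueError(f"unknown held-out id(s): {unknown}")
    remaining = [r for r in records if r.id not in set(held_out_ids)]
    if len(remaining) < 5:
        raise ValueError("fewer than 5 records remain after holdout")
    remaining_seqs = {r.sequence for r in remaining}
    for h in held_out_ids:
        if by_id[h].sequence in remaining_seqs:
            logger.warning("held-out %s duplicates a remaining training "
                           "sequence; recovery is degenerate", h)

    result = run_generation_round(remaining, scaffold, config, alphabet)

    by_score = sorted(result.pool.novel, key=lambda s: -s.score)
    score_rank_of = {s.sequence: k + 1 for k, s in enumerate(by_score)}
    order = np.argsort(result.predictions, kind="stable")
    novel_seqs = [s.sequence for s in result.pool.novel]
    ki_rank_of = {novel_seqs[idx]: k + 1 for k, idx in enumerate(order)}
    selected_seqs = {s for s, _, _ in result.selected}

    regenerated = []
    score_rank: dict[str, int | None] = {}
    ki_rank: dict[str, int | None] = {}
    for h in held_out_ids:
        seq = by_id[h].sequence
        score_rank[h] = score_rank_of.get(seq)
        ki_rank[h] = ki_rank_of.get(seq)
        if seq in selected_seqs or seq in remaining_seqs:
            regenerated.append(h)
    return RecoveryReport(held_out_ids=list(held_out_ids),
                          regenerated=regenerated,
                          pool_size=len(result.pool.novel),
                          selected_size=len(result.selected),
                          score_rank=score_rank, ki_rank=ki_rank,
                          result=result)


def design_candidates(logo: FrequencyMatrix, scaffold: Scaffold,
                      runner_up_fraction: float = 0.5,
                      max_candidates: int = 8) -> list[str]:
    """Frequency-guided candidate design from a selected-pool logo.

    The consensus (top-frequency residue at each variable position, scaffold
    residues at fixed positions) comes first. Positions whose runner-up
    frequency reaches ``runner_up_fraction`` times the top frequency are
    ambiguous; they are branched into top/runner-up alternatives in
    descending runner-up-ratio order, growing the candidate list
    Cartesian-style up to ``max_candidates``. Frequency ties break toward
    the alphabetically earlier residue. Three binary-ambiguous positions
    therefore yield the published-style set of eight variants.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be >= 1")
    if not 0 < runner_up_fraction <= 1:
        raise ValueError("runner_up_fraction must be in (0, 1]")
    symbols = logo.alphabet.symbols
    consensus = list("?" * scaffold.L)
    for pos, sym in scaffold.fixed.items():
        consensus[pos - 1] = sym
    branches: list[tuple[float, int, str, str]] = []  # (ratio, pos, top, runner)
    for pos in scaffold.variable_positions:
        row = logo.freqs[pos - 1]
        order = np.lexsort((np.arange(len(row)), -row))  # freq desc, alpha asc
        top, runner = order[0], order[1]
        consensus[pos - 1] = symbols[top]
        if row[top] > 0 and row[runner] >= runner_up_fraction * row[top]:
            branches.append((float(row[runner] / row[top]), pos,
                             symbols[top], symbols[runner]))
    branches.sort(key=lambda t: (-t[0], t[1]))

    candidates = ["".join(consensus)]
    for _ratio, pos, _top, runner in branches:
        if len(candidates) >= max_candidates:
            break
        candidates += [c[:pos - 1] + runner + c[pos:] for c in candidates]
    return candidates[:max_candidates]


def fold_change(ki_a: float, ki_b: float) -> float:
    """Dimensionless potency ratio ki_a / ki_b (>1 means b is more potent)."""
    if not (ki_a > 0 and ki_b > 0):
        raise ValueError("Ki values must be positive")
    return ki_a / ki_b


def fold_change_rounded(ki_a: float, ki_b: float) -> float:
    """Fold change rounded to one decimal, the convention used in reporting."""
    return round(fold_change(ki_a, ki_b), 1)
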