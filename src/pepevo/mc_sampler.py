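"""Metropolis Monte Carlo generation of scaffold-constrained sequences.

The fitted Potts score plays the role of a (negated) effective energy: a
single-site mutation at a variable position is proposed uniformly and
accepted with probability min(1, exp((S' - S)/T)). At stationarity the chain
samples the Boltzmann distribution P(sigma) ~ exp(S(sigma)/T) restricted to
scaffold-conformant sequences, which is verified against exact enumeration on
tiny models in the test suite.

Score updates are incremental (O(L) per proposal); the full O(L^2) rescore is
used only for verification. Reproducibility: chain c uses
``numpy.random.default_rng((seed + c) mod 2^31)``, and proposal randomness is
drawn in fixed-size blocks, so a given seed yields a bitwise-identical pool
within this implementation (ports using another generator can only match
distributionally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .plmdca import PottsModel, SequenceScore
from .seq_core import Alphabet, Scaffold

logger = logging.getLogger("pepevo")

_BLOCK = 1024  # proposals drawn per RNG block; fixed for reproducibility


@dataclass
class SamplerConfig:
    """Chain layout and acceptance-rule parameters.

    The defaults (50 chains x 2000 steps, burn-in 500, thinning 10) are sized
    so a desk run yields on the order of 10^4 recorded states — the scale of
    the published campaigns (~23600 generated sequences), whose exact counts
    depend on unreported run lengths and are not reproduction targets.
    Temperature defaults to 1 so the Potts score is used as-is.
    """

    n_chains: int = 50
    steps: int = 2000
    burn_in: int = 500
    thinning: int = 10
    temperature: float = 1.0
    seed: int = 0
    init: str = "random_training_sequence"  # or "random_scaffold_conformant"

    def __post_init__(self) -> None:
        if not self.steps > self.burn_in >= 0:
            raise ValueError("need steps > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")
        if self.init not in ("random_training_sequence",
                             "random_scaffold_conformant"):
            raise ValueError(f"unknown init mode {self.init!r}")

    def to_dict(self) -> dict:
        return {"n_chains": self.n_chains, "steps": self.steps,
                "burn_in": self.burn_in, "thinning": self.thinning,
                "temperature": self.temperature, "seed": self.seed,
                "init": self.init}


@dataclass
class SamplePool:
    """Deduplicated recorded states of a sampling run.

    ``samples`` keeps unique sequences in first-seen order with their exact
    Potts scores; ``counts`` carries the recorded multiplicities, so the
    empirical visit distribution is recoverable. ``novel`` is the subset not
    present in the excluded (training) set.
    """

    samples: list[SequenceScore]
    counts: list[int]
    n_proposed: int
    n_accepted: int
    novel: list[SequenceScore]
    config: SamplerConfig
    model_digest: str = ""

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0

    @property
    def total_recorded(self) -> int:
        return int(sum(self.counts))

    @property
    def is_empty(self) -> bool:
        return not self.samples

    def empirical_distribution(self) -> dict[str, float]:
        total = self.total_recorded
        return {s.sequence: c / total
                for s, c in zip(self.samples, self.counts)}

    def mean_score(self) -> float:
        total = self.total_recorded
        return sum(s.score * c for s, c in zip(self.samples, self.counts)) / total


def propose_mutation(sequence: str, scaffold: Scaffold,
                     rng: np.random.Generator,
                     alphabet: Alphabet | None = None) -> str:
    """Mutate one uniformly chosen variable position to a different residue.

    Fixed scaffold positions are never touched; the proposal is symmetric
    (uniform over position x new-residue), as the Metropolis rule requires.
    """
    alphabet = alphabet or Alphabet()
    variable = scaffold.variable_positions
    if not variable:
        raise ValueError("scaffold has no variable positions")
    pos = variable[rng.integers(len(variable))] - 1
    current = alphabet.index(sequence[pos])
    # uniform over the q-1 residues != current
    new = int(rng.integers(alphabet.q - 1))
    if new >= current:
        new += 1
    return sequence[:pos] + alphabet.symbols[new] + sequence[pos + 1:]


def _delta_score(model: PottsModel, Jfull: np.ndarray, sigma: np.ndarray,
                 pos: int, new: int) -> float:
    """Score change for mutating 0-based ``pos`` to residue ``new``: O(L)."""
    old = sigma[pos]
    d = model.h[pos, new] - model.h[pos, old]
    # diagonal block is zero, so including j == pos is harmless
    d += Jfull[pos, np.arange(len(sigma)), new, sigma].sum()
    d -= Jfull[pos, np.arange(len(sigma)), old, sigma].sum()
    return float(d)


def metropolis_step(model: PottsModel, current: SequenceScore,
                    temperature: float, rng: np.random.Generator
                    ) -> tuple[SequenceScore, bool]:
    """One proposal + accept/reject; returns the (possibly new) state.

    Uphill moves (higher score) are always accepted; downhill moves with
    probability exp(dS/T). The returned score is updated incrementally.
    """
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    if not np.isfinite(current.score):
        raise ValueError("non-finite current score")
    scaffold, alphabet = model.scaffold, model.alphabet
    Jfull = model.full_coupling_tensor()
    sigma = alphabet.encode(current.sequence)
    variable = np.array(scaffold.variable_positions) - 1
    pos = int(variable[rng.integers(len(variable))])
    new = int(rng.integers(alphabet.q - 1))
    if new >= sigma[pos]:
        new += 1
    d = _delta_score(model, Jfull, sigma, pos, new)
    if d >= 0 or rng.random() < np.exp(d / temperature):
        seq = (current.sequence[:pos] + alphabet.symbols[new]
               + current.sequence[pos + 1:])
        return SequenceScore(sequence=seq, score=current.score + d), True
    return current, False


def _run_chain(model: PottsModel, Jfull: np.ndarray, start: np.ndarray,
               config: SamplerConfig, rng: np.random.Generator,
               record: dict[str, list]) -> tuple[int, int]:
    """Run one chain, accumulating thinned post-burn-in states into ``record``.

    ``record`` maps sequence -> [score, count]. Returns (proposed, accepted).
    """
    L = model.L
    q = model.q
    variable = np.array(model.scaffold.variable_positions) - 1
    sigma = start.copy()
    score = float(model.score(sigma))
    arange_L = np.arange(L)
    h = model.h
    invT = 1.0 / config.temperature
    accepted = 0
    step = 0
    while step < config.steps:
        block = min(_BLOCK, config.steps - step)
        pos_idx = rng.integers(len(variable), size=block)
        res_idx = rng.integers(q - 1, size=block)
        unif = rng.random(block)
        for b in range(block):
            pos = variable[pos_idx[b]]
            old = sigma[pos]
            new = res_idx[b]
            if new >= old:
                new += 1
            d = (h[pos, new] - h[pos, old]
                 + Jfull[pos, arange_L, new, sigma].sum()
                 - Jfull[pos, arange_L, old, sigma].sum())
            if d >= 0 or unif[b] < np.exp(d * invT):
                sigma[pos] = new
                score += d
                accepted += 1
            step_now = step + b
            if (step_now >= config.burn_in
                    and (step_now - config.burn_in) % config.thinning == 0):
                seq = model.alphabet.decode(sigma)
                entry = record.get(seq)
                if entry is None:
                    record[seq] = [score, 1]
                else:
                    entry[1] += 1
        step += block
    return config.steps, accepted


def sample_sequences(model: PottsModel, scaffold: Scaffold,
                     config: SamplerConfig,
                     exclude: set[str] | frozenset[str] = frozenset(),
                     init_sequences: list[str] | None = None) -> SamplePool:
    """Run independent Metropolis chains and collect a deduplicated pool.

    ``exclude`` (typically the training family) defines the ``novel`` subset;
    ``init_sequences`` supplies starting points when
    ``config.init == 'random_training_sequence'``. An empty pool after
    exclusion yields an explicit empty result, never an exception.
    """
    if scaffold != model.scaffold:
        raise ValueError("sampler scaffold does not match model scaffold")
    if config.init == "random_training_sequence" and not init_sequences:
        raise ValueError("init='random_training_sequence' requires init_sequences")
    Jfull = model.full_coupling_tensor()
    record: dict[str, list] = {}
    n_proposed = 0
    n_accepted = 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng((config.seed + chain) % 2 ** 31)
        if config.init == "random_training_sequence":
            start_seq = init_sequences[rng.integers(len(init_sequences))]
        else:
            start_seq = scaffold.random_conformant(rng, model.alphabet)
        start = model.alphabet.encode(start_seq)
        prop, acc = _run_chain(model, Jfull, start, config, rng, record)
        n_proposed += prop
        n_accepted += acc
    samples = [SequenceScore(sequence=s, score=v[0]) for s, v in record.items()]
    counts = [v[1] for v in record.values()]
    excluded = set(exclude)
    novel = [s for s in samples if s.sequence not in excluded]
    pool = SamplePool(samples=samples, counts=counts, n_proposed=n_proposed,
                      n_accepted=n_accepted, novel=novel, config=config,
                      model_digest=model.digest())
    if pool.is_empty or not novel:
        logger.warning("sampling produced an empty %s pool",
                       "sample" if pool.is_empty else "novel")
    logger.info("MC sampling: %d recorded states, %d unique, %d novel, "
                "acceptance %.3f", pool.total_recorded, len(samples),
                len(novel), pool.acceptance_rate)
    return pool


def export_pool_tsv(pool: SamplePool, path) -> None:
    """TSV export: sequence, score, recorded count."""
    import pandas as pd

    pd.DataFrame({"sequence": [s.sequence for s in pool.samples],
                  "score": [s.score for s in pool.samples],
                  "count": pool.counts}).to_csv(path, sep="\t", index=False)
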