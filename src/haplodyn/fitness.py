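"""Pseudo-log-likelihood-ratio (PLLR) scoring of protein variants.

A *position scorer* assigns, for a protein sequence, one log-probability per
position: the probability the model gives to the residue actually present.
The pseudo-log-likelihood of a sequence is the sum of these, and the PLLR of
a variant against its wild type is

    PLLR = PLL(variant) - PLL(wild type),

averaged over an ensemble of scorers.  Positive PLLR means the variant
sequence is more plausible (less disruptive) under the model; negative PLLR
flags a potentially harmful change.  The wild-type sequence scores 0 against
itself by construction and is included when summarising per-transcript score
variability (max minus min of the haplotype scores).

The package builds and tests against deterministic toy scorers whose full
per-position probability rows are known (see ``haplodyn.synthetic``); an
adapter for the ESM-1v protein language model ensemble lives in
``haplodyn.esm_adapter`` and activates only when that package is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "PositionScorer",
    "ToyScorer",
    "FitnessScore",
    "pseudo_log_likelihood",
    "pllr",
    "score_variability",
    "cohort_score_table",
    "load_exo5_reference_scores",
    "AlphabetError",
    "SequenceLengthError",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class AlphabetError(ValueError):
    """Sequence contains a residue outside the scorer's alphabet."""


class SequenceLengthError(ValueError):
    """Sequence length is incompatible with the scorer or comparison."""


@runtime_checkable
class PositionScorer(Protocol):
    """Contract: ``score(seq)`` returns one log-probability per position —
    that of the residue present.  ``identifier`` names the ensemble member."""

    identifier: str

    def score(self, sequence: str) -> np.ndarray: ...


@dataclass
class ToyScorer:
    """Deterministic positionwise scorer backed by an explicit log-probability
    table of shape (length, len(alphabet)); rows exponentiate to 1.

    Because each position is scored independently of context, the masked and
    plain scoring modes coincide for this scorer.
    """

    alphabet: str
    log_table: np.ndarray
    identifier: str = "toy"
    normalized: bool = True

    def __post_init__(self) -> None:
        self.log_table = np.asarray(self.log_table, dtype=float)
        if self.log_table.ndim != 2 or self.log_table.shape[1] != len(self.alphabet):
            raise ValueError("log_table must be (length, alphabet size)")
        if self.normalized:
            rowsums = np.exp(self.log_table).sum(axis=1)
            if not np.allclose(rowsums, 1.0, atol=1e-6):
                raise ValueError(
                    "each row's probabilities must sum to 1 "
                    "(pass normalized=False for hand-rounded tables)"
                )
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    @property
    def length(self) -> int:
        return self.log_table.shape[0]

    def _validate(self, sequence: str) -> list[int]:
        if len(sequence) != self.length:
            raise SequenceLengthError(
                f"scorer expects length {self.length}, got {len(sequence)}"
            )
        try:
            return [self._index[a] for a in sequence]
        except KeyError as err:
            raise AlphabetError(f"residue {err.args[0]!r} not in alphabet") from None

    def score(self, sequence: str) -> np.ndarray:
        idx = self._validate(sequence)
        return self.log_table[np.arange(self.length), idx]

    def score_masked(self, sequence: str) -> np.ndarray:
        # positionwise model: masking a position cannot change its row
        return self.score(sequence)


@dataclass(frozen=True)
class FitnessScore:
    """Ensemble PLLR of one haplotype protein against the wild type."""

    haplotype_id: str
    pllr: float
    components: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.components and not np.isclose(self.pllr, float(np.mean(self.components))):
            raise ValueError("pllr must equal the mean of per-model components")


def pseudo_log_likelihood(scorer: PositionScorer, sequence: str,
                          mode: str = "plain") -> float:
    """Sum of per-position log-probabilities of the residues present.

    ``mode='masked'`` requests masked-marginal scoring from scorers that
    support it (``score_masked``); the default is a single unmasked pass.
    """
    if not sequence:
        raise SequenceLengthError("sequence must be non-empty")
    if mode == "masked":
        fn = getattr(scorer, "score_masked", None)
        if fn is None:
            raise ValueError(f"scorer {scorer.identifier} does not support masked scoring")
        logp = fn(sequence)
    elif mode == "plain":
        logp = scorer.score(sequence)
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    logp = np.asarray(logp, dtype=float)
    if logp.shape != (len(sequence),):
        raise ValueError("scorer returned wrong number of positions")
    return float(logp.sum())


def pllr(ensemble: Iterable[PositionScorer], wt: str, alt: str,
         haplotype_id: str = "", mode: str = "plain") -> FitnessScore:
    """Ensemble-averaged PLLR of ``alt`` against ``wt``.

    Both sequences must have equal length (substitution-only haplotypes);
    comparing sequences of different length is refused rather than
    length-normalised.
    """
    if len(wt) != len(alt):
        raise SequenceLengthError(
            f"wild-type ({len(wt)}) and variant ({len(alt)}) lengths differ; "
            "only substitution haplotypes are comparable"
        )
    components = tuple(
        pseudo_log_likelihood(m, alt, mode) - pseudo_log_likelihood(m, wt, mode)
        for m in ensemble
    )
    if not components:
        raise ValueError("ensemble must contain at least one scorer")
    return FitnessScore(haplotype_id=haplotype_id, pllr=float(np.mean(components)),
                        components=components)


def score_variability(scores: Iterable[FitnessScore | float]) -> float:
    """Maximum pairwise difference (max minus min) of a transcript's PLLR
    scores, wild type (0) included by the caller."""
    values = [s.pllr if isinstance(s, FitnessScore) else float(s) for s in scores]
    if not values:
        raise ValueError("need at least one score")
    return float(max(values) - min(values))


def load_exo5_reference_scores() -> pd.DataFrame:
    """Published ESM-1v ensemble PLLR scores of the common EXO5 haplotype
    proteins against the wild type (haplotype 1, scored 0 by construction):
    G172V, G172V+D115N and L151P.  These serve as fixed inputs for
    summary statistics such as the transcript score variability."""
    from importlib.resources import files

    with (files("haplodyn") / "data" / "exo5_pllr.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_score_table(gene_tables: dict[str, dict[str, list[FitnessScore | float]]],
                       threshold: float = 1.0) -> dict:
    """Summarise PLLR scores across a cohort of genes.

    ``gene_tables`` maps gene -> transcript -> list of scores (the wild-type
    entry at 0 included).  Returns per-haplotype and per-transcript frames
    plus summary fractions; the haplotype-share statistic is reported both
    with and without the wild-type rows, since a wild type trivially scores 0.
    """
    if not gene_tables:
        raise ValueError("empty cohort")
    hap_rows, var_rows = [], []
    for gene, transcripts in gene_tables.items():
        for transcript, scores in transcripts.items():
            values = [s.pllr if isinstance(s, FitnessScore) else float(s) for s in scores]
            for k, v in enumerate(values):
                hap_rows.append({"gene": gene, "transcript": transcript,
                                 "haplotype": k, "pllr": v,
                                 "is_wildtype": v == 0.0 and k == 0})
            var_rows.append({"gene": gene, "transcript": transcript,
                             "n_haplotypes": len(values),
                             "variability": score_variability(values)})
    haps = pd.DataFrame(hap_rows)
    var = pd.DataFrame(var_rows)
    multi = var[var["n_haplotypes"] > 1]
    nonwt = haps[~haps["is_wildtype"]]
    return {
        "haplotype_scores": haps,
        "transcript_variability": var,
        "frac_high_impact_all": float((haps["pllr"].abs() > threshold).mean()),
        "frac_high_impact_excl_wt": float((nonwt["pllr"].abs() > threshold).mean())
        if len(nonwt) else 0.0,
        "frac_variable_transcripts": float((multi["variability"] > threshold).mean())
        if len(multi) else 0.0,
    }
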