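"""Strategy registry and orchestration.

A *variation* fixes the similarity technique (F/K/L/P/Q) and the
guide-tree builder (NJ/SLMAX/SLMIN/UPGMA): 5 × 4 = 20 variations.  A
*strategy* adds one of the four heuristic classes — P (progressive
only), C (consistency transformation before the profile stage), I
(iterative refinement after it), CI (both) — for 80 strategies in all.

``run_strategy`` executes the stages a class requires, reusing Stage-1
and Stage-2 artifacts across strategies through a content-addressed
cache, so e.g. comparing two guide-tree builders computes the similarity
matrix once.  ``run_benchmark`` scores many strategies over many
instances and emits the tidy score store consumed by
:mod:`msaforge.stats_compare`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import pandas as pd

from . import __version__
from .consistency import build_primary_library, consistency_transform
from .evaluate import developer_score, identity, identity_group
from .fixtures import FamilyInstance
from .guidetree import GuideTree, build_nj, build_slink, build_upgma
from .profile_align import GapModel, MatrixChooser, compute_sequence_weights, progressive_align
from .refine import RefinementConfig, pair_weights, refine, wsp
from .seq_core import Alignment, Sequence, SubstitutionMatrix, read_alignment, read_fasta
from .similarity import build_similarity_matrix, default_hmm_params

logger = logging.getLogger("msaforge")

SCORINGS = ("F", "K", "L", "P", "Q")
TREES = ("NJ", "SLMAX", "SLMIN", "UPGMA")
CLASSES = ("C", "CI", "I", "P")  # lexicographic; the canonical enumeration order


@dataclass(frozen=True)
class StrategyId:
    """One of the 80 strategies: scoring × tree × heuristic class."""

    scoring: str
    tree: str
    cls: str

    def __post_init__(self) -> None:
        if self.scoring not in SCORINGS:
            raise ValueError(f"unknown scoring technique {self.scoring!r}")
        if self.tree not in TREES:
            raise ValueError(f"unknown tree builder {self.tree!r}")
        if self.cls not in CLASSES:
            raise ValueError(f"unknown heuristic class {self.cls!r}")

    @property
    def variation(self) -> str:
        return f"{self.scoring}.{self.tree}"

    @property
    def text(self) -> str:
        return f"{self.variation}+{self.cls}"

    @classmethod
    def parse(cls, text: str) -> "StrategyId":
        try:
            variation, klass = text.split("+")
            scoring, tree = variation.split(".")
        except ValueError as exc:
            raise ValueError(f"bad strategy text {text!r}") from exc
        return cls(scoring, tree, klass)

    def __str__(self) -> str:
        return self.text


def enumerate_variations() -> list[str]:
    return [f"{s}.{t}" for s, t in product(SCORINGS, TREES)]


def enumerate_strategies() -> list[StrategyId]:
    """All 80 strategies in (scoring, tree, class) lexicographic order."""
    return [StrategyId(s, t, c) for s, t, c in product(SCORINGS, TREES, CLASSES)]


@dataclass
class PipelineConfig:
    """All tunables of a framework run, with Clustal-W-flavoured defaults."""

    matrix_name: str = "BLOSUM62"
    adaptive_matrix: bool = False
    gap_open: float = 10.0
    gap_extend: float = 0.2
    sim_gap_open: float = 10.0
    sim_gap_extend: float = 0.5
    quick_k: int = 1
    kmers_k: int = 3
    hmm_delta: float = 0.02
    hmm_epsilon: float = 0.4
    library_mode: str = "posterior"
    library_epsilon: float = 0.01
    library_scale: float | str = "auto"
    position_specific_gaps: bool = True
    terminal_gaps_free: bool = True
    refine_enabled: bool = True
    refine_max_iterations: int = 100
    refine_objective: str = "wsp"
    seed: int = 0

    def gap_model(self) -> GapModel:
        return GapModel(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            position_specific=self.position_specific_gaps,
            terminal_free=self.terminal_gaps_free,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["library_scale"] = str(self.library_scale)
        return d


class StageCache:
    """Content-addressed cache for stage artifacts shared across strategies."""

    def __init__(self) -> None:
        self._store: dict[str, object] = {}
        self.hits = 0
        self.misses = 0
        #: shared pair-HMM posterior matrices, keyed by sorted id pairs
        self.posteriors: dict = {}

    @staticmethod
    def key(seqs: list[Sequence], stage: str, params: object) -> str:
        payload = repr(
            (tuple((s.id, s.residues) for s in seqs), stage, repr(params))
        ).encode()
        return hashlib.sha256(payload).hexdigest()

    def get_or_compute(self, key: str, compute):
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        value = compute()
        self._store[key] = value
        return value


def _build_tree(sim, builder: str) -> GuideTree:
    if builder == "NJ":
        return build_nj(sim)
    if builder == "UPGMA":
        return build_upgma(sim)
    return build_slink(sim, builder)


def run_strategy(
    seqs: list[Sequence],
    strategy: StrategyId | str,
    config: PipelineConfig | None = None,
    cache: StageCache | None = None,
) -> tuple[Alignment, dict]:
    """Run one strategy end to end; returns (alignment, provenance record)."""
    if isinstance(strategy, str):
        strategy = StrategyId.parse(strategy)
    config = config or PipelineConfig()
    cache = cache if cache is not None else StageCache()
    try:
        return _run_strategy(seqs, strategy, config, cache)
    except Exception as exc:
        raise RuntimeError(f"strategy {strategy} failed: {exc}") from exc


def _run_strategy(
    seqs: list[Sequence],
    strategy: StrategyId,
    config: PipelineConfig,
    cache: StageCache,
) -> tuple[Alignment, dict]:
    matrix = SubstitutionMatrix.load(config.matrix_name)
    hmm = default_hmm_params(config.hmm_delta, config.hmm_epsilon)

    sim_params = (
        strategy.scoring,
        config.matrix_name,
        config.sim_gap_open,
        config.sim_gap_extend,
        config.quick_k,
        config.kmers_k,
        config.hmm_delta,
        config.hmm_epsilon,
    )
    sim = cache.get_or_compute(
        cache.key(seqs, "similarity", sim_params),
        lambda: build_similarity_matrix(
            seqs,
            strategy.scoring,
            matrix=matrix,
            gap_open=config.sim_gap_open,
            gap_extend=config.sim_gap_extend,
            k=config.quick_k if strategy.scoring == "Q" else config.kmers_k,
            hmm_params=hmm,
            posterior_cache=cache.posteriors,
        ),
    )
    tree = cache.get_or_compute(
        cache.key(seqs, "guidetree", (strategy.tree,) + sim_params),
        lambda: _build_tree(sim, strategy.tree),
    )

    lib = None
    if strategy.cls in ("C", "CI"):
        lib_params = (
            config.library_mode,
            config.library_epsilon,
            config.hmm_delta,
            config.hmm_epsilon,
            config.matrix_name,
        )
        primary = cache.get_or_compute(
            cache.key(seqs, "library", lib_params),
            lambda: build_primary_library(
                seqs,
                config.library_mode,
                hmm_params=hmm,
                matrix=matrix,
                epsilon=config.library_epsilon,
                posterior_cache=cache.posteriors,
            ),
        )
        lib = cache.get_or_compute(
            cache.key(seqs, "library_extended", lib_params),
            lambda: consistency_transform(primary),
        )

    chooser = (
        MatrixChooser(sim=sim) if config.adaptive_matrix else MatrixChooser(fixed=matrix)
    )
    gap_model = config.gap_model()
    aln = progressive_align(
        seqs, tree, chooser, gap_model, lib, config.library_scale
    )

    refined = False
    if strategy.cls in ("I", "CI") and config.refine_enabled:
        aln = refine(
            aln,
            tree,
            matrix,
            gap_model,
            lib,
            config.library_scale,
            RefinementConfig(
                max_iterations=config.refine_max_iterations,
                objective=config.refine_objective,
            ),
        ).reorder([s.id for s in seqs])
        refined = True

    weights = compute_sequence_weights(tree)
    provenance = {
        "strategy": strategy.text,
        "stages": {
            "similarity": strategy.scoring,
            "guidetree": strategy.tree,
            "consistency": strategy.cls in ("C", "CI"),
            "refinement": refined,
        },
        "config": config.to_dict(),
        "wsp": wsp(aln, matrix, pair_weights(weights, aln.ids)),
        "version": __version__,
    }
    return aln, provenance


# ---------------------------------------------------------------------------
# benchmark runner

@dataclass
class BenchmarkInstance:
    """One problem: unaligned sequences plus the reference alignment."""

    instance_id: str
    sequences: list[Sequence]
    reference: Alignment
    benchmark: str = "synthetic"

    @classmethod
    def from_dir(cls, path: str | Path, benchmark: str = "synthetic") -> "BenchmarkInstance":
        path = Path(path)
        return cls(
            instance_id=path.name,
            sequences=read_fasta(path / "sequences.fasta"),
            reference=read_alignment(path / "reference.fasta"),
            benchmark=benchmark,
        )

    @classmethod
    def from_family(cls, fam: FamilyInstance, benchmark: str = "synthetic") -> "BenchmarkInstance":
        return cls(fam.instance_id, fam.sequences, fam.reference, benchmark)


def load_dataset(root: str | Path, benchmark: str = "synthetic") -> list[BenchmarkInstance]:
    """Load every instance directory under ``root`` (sorted by name)."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "sequences.fasta").exists())
    if not dirs:
        raise ValueError(f"no instance directories under {root}")
    return [BenchmarkInstance.from_dir(d, benchmark) for d in dirs]


def run_benchmark(
    instances: list[BenchmarkInstance],
    strategies: list[StrategyId] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score strategies over instances; failures skip the instance.

    Returns the tidy score store with one row per (instance, strategy):
    benchmark, band, instance, variation, cls, strategy, ds, identity,
    wsp.
    """
    strategies = strategies or enumerate_strategies()
    config = config or PipelineConfig()
    matrix = SubstitutionMatrix.load(config.matrix_name)
    records = []
    for inst in instances:
        cache = StageCache()
        try:
            ref_identity = identity(inst.reference)
            band = identity_group(ref_identity)
        except ValueError as exc:
            logger.warning("skipping instance %s: %s", inst.instance_id, exc)
            continue
        for strat in strategies:
            try:
                aln, prov = run_strategy(inst.sequences, strat, config, cache)
                ds = developer_score(aln, inst.reference)
            except (RuntimeError, ValueError) as exc:
                logger.warning(
                    "instance %s strategy %s failed: %s", inst.instance_id, strat, exc
                )
                continue
            records.append(
                {
                    "benchmark": inst.benchmark,
                    "band": band,
                    "instance": inst.instance_id,
                    "variation": strat.variation,
                    "cls": strat.cls,
                    "strategy": strat.text,
                    "ds": ds,
                    "identity": ref_identity,
                    "wsp": prov["wsp"],
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "benchmark", "band", "instance", "variation", "cls",
            "strategy", "ds", "identity", "wsp",
        ],
    )


def save_store(store: pd.DataFrame, path: str | Path) -> None:
    store.to_csv(path, sep="\t", index=False)


def load_store(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_provenance(provenance: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2)
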