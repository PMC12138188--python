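"""End-to-end pairwise coevolution scan.

Ties the pipeline together: read and validate inputs, normalise the tree,
filter features by abundance, enumerate the comparison plan, fit every
pair (optionally across worker processes), screen validity, and write the
Z/P matrices plus the normalised tree.  Results are gathered in plan
order, and each fit is deterministic, so the written numbers are identical
for any worker count.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from . import io as ccm_io
from .inference import DEFAULT_Z_CAP, FitResult, fit_ccm, validity_screen
from .model import TreeIndex
from .trees import normalize_tree, read_newick, write_newick


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one scan; a fixed seed makes the run reproducible."""

    feature_path: str | Path
    tree_path: str | Path
    out_prefix: str | Path = "ccm"
    cores: int = 1  # -1 = all available
    min_count: int = 0
    max_count: int | None = None  # None = number of genomes
    from_prefixes: tuple[str, ...] = ()
    to_prefixes: tuple[str, ...] = ()
    seed: int = 42
    strict_binary: bool = False
    z_cap: float = DEFAULT_Z_CAP
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.cores != -1 and self.cores < 1:
            raise ValueError("cores must be -1 (all) or >= 1")


@dataclass
class RunSummary:
    """Diagnostics of a completed scan."""

    n_genomes: int
    n_features_input: int
    n_features_removed: int
    n_features_tested: int
    cores_used: int
    tree_operations: list[str]
    pairs_tested: int
    pairs_invalid: int
    warnings: list[str] = field(default_factory=list)
    z_path: Path | None = None
    p_path: Path | None = None
    tree_path: Path | None = None

    def print(self, stream=None) -> None:
        stream = stream or sys.stdout
        w = stream.write
        w(f"genomes: {self.n_genomes}\n")
        w(f"features (input): {self.n_features_input}\n")
        w(f"features removed by abundance filter: {self.n_features_removed}\n")
        w(f"features retained for testing: {self.n_features_tested}\n")
        w(f"cores used: {self.cores_used}\n")
        ops = ", ".join(self.tree_operations) or "none"
        w(f"tree operations: {ops}\n")
        w(f"pairs tested: {self.pairs_tested}\n")
        w(f"pairs invalid: {self.pairs_invalid}\n")
        for warning in self.warnings:
            w(f"warning: {warning}\n")
        if self.z_path:
            w(f"Z matrix: {self.z_path}\n")
        if self.p_path:
            w(f"P matrix: {self.p_path}\n")
        if self.tree_path:
            w(f"tree used: {self.tree_path}\n")


def _fit_pair(index, data, pair, z_cap, ridge):
    """Worker: fit one pair; a raising fit is recorded invalid, not fatal."""
    try:
        fit = fit_ccm(index, data[list(pair)], ridge=ridge)
        return pair, validity_screen(fit, z_cap)
    except Exception as exc:  # record and continue; the scan must not die
        return pair, exc


def run(config: RunConfig, quiet: bool = False) -> RunSummary:
    """Execute a full scan and write ``<prefix>.{zscores,pvalues}.tsv`` and
    ``<prefix>.tree.nwk``."""
    table = ccm_io.read_feature_table(config.feature_path)
    tree = read_newick(Path(config.tree_path))
    tree, tree_ops = normalize_tree(
        tree,
        table.genome_ids,
        strict_binary=config.strict_binary,
        seed=config.seed,
    )

    max_count = config.max_count
    if max_count is None:
        max_count = table.shape[0]
    filtered, report = ccm_io.abundance_filter(table, config.min_count, max_count)
    plan = ccm_io.enumerate_pairs(
        filtered.feature_names, config.from_prefixes, config.to_prefixes
    )

    index = TreeIndex.from_tree(tree)
    n_jobs = config.cores
    cores_used = joblib.cpu_count() if n_jobs == -1 else n_jobs
    data = filtered.data
    outputs = joblib.Parallel(n_jobs=n_jobs)(
        joblib.delayed(_fit_pair)(index, data, pair, config.z_cap, config.ridge)
        for pair in plan.pairs
    )

    results: dict[tuple[str, str], tuple[float, float] | None] = {}
    invalid = 0
    warnings = list(plan.warnings)
    for pair, fit in outputs:
        if isinstance(fit, Exception):
            results[pair] = None
            invalid += 1
            warnings.append(f"pair {pair[0]}~{pair[1]} failed: {fit}")
        elif isinstance(fit, FitResult) and fit.valid:
            results[pair] = (fit.z_interaction, fit.p_interaction)
        else:
            results[pair] = None
            invalid += 1

    z_path, p_path = ccm_io.write_matrices(
        results, filtered.feature_names, config.out_prefix
    )
    tree_out = Path(f"{config.out_prefix}.tree.nwk")
    write_newick(tree, tree_out)

    summary = RunSummary(
        n_genomes=table.shape[0],
        n_features_input=table.shape[1],
        n_features_removed=report.n_removed,
        n_features_tested=filtered.shape[1],
        cores_used=cores_used,
        tree_operations=tree_ops,
        pairs_tested=plan.n_pairs,
        pairs_invalid=invalid,
        warnings=warnings,
        z_path=z_path,
        p_path=p_path,
        tree_path=tree_out,
    )
    if not quiet:
        summary.print()
    return summary
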