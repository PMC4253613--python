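"""File I/O and the end-to-end run driver.

Matrices are delimited text with a header row of variable labels and a
first column of observation labels; the delimiter is sniffed unless given.
Truth and group files are two-column TSVs (label, id).  A run writes the
tree (Newick + flat merge table), the tightness and significance tables,
the partition, and a JSON manifest that records the configuration, seed
and library versions needed to reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import TBEST
from .evaluation import best_branch_partition, corrected_rand, rand_index, relative_cri
from .partition import partition_labels
from .tree import Dendrogram

logger = logging.getLogger("tbest")

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_labels",
    "read_groups",
    "run_to_dir",
    "evaluate_to_report",
]


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a labeled observations x variables matrix from CSV/TSV."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {bad}; remove or impute them before clustering")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("row and column labels must be unique")
    return df.astype(float)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (observation_label, id) -> Series indexed by label."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (label, id)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


read_groups = read_labels


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    input: str
    metric: str = "euclidean"
    linkage: str = "complete"
    statistic: str = "parent"
    scheme: str = "columns"
    groups: str | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    use_evt: bool = True
    tail_fraction: float = 0.1
    correction: str = "sidak"
    seed: int | None = None
    outdir: str = "tbest_out"


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_to_dir(config: RunConfig) -> TBEST:
    """Run the pipeline per ``config`` and write all outputs into ``config.outdir``."""
    t0 = time.time()
    X = read_matrix(config.input)
    logger.info("loaded %d observations x %d variables from %s", *X.shape, config.input)
    group_ids = None
    if config.scheme == "grouped":
        if config.groups is None:
            raise ValueError("scheme='grouped' requires --groups")
        groups = read_groups(config.groups)
        missing = [c for c in X.columns if c not in groups.index]
        if missing:
            raise ValueError(f"variables missing from the groups file: {missing[:10]}")
        group_ids = groups.loc[X.columns].to_numpy()
    model = TBEST(
        metric=config.metric,
        linkage=config.linkage,
        statistic=config.statistic,
        scheme=config.scheme,
        groups=group_ids,
        n_perm=config.n_perm,
        alpha=config.alpha,
        use_evt=config.use_evt,
        tail_fraction=config.tail_fraction,
        correction=config.correction,
        random_state=config.seed,
    ).fit(X)
    logger.info(
        "tree: %d leaves, %d tested nodes; %d permutations; %d-part partition (significant=%s)",
        model.tree_.n_leaves,
        len(model.significance_),
        config.n_perm,
        model.n_parts_,
        model.is_significant_,
    )

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.newick").write_text(model.tree_.to_newick() + "\n")
    model.tree_.merge_table().to_csv(out / "merges.tsv", sep="\t", index=False)
    tt = model.tightness_.copy()
    tt.insert(2, "statistic", model.statistic)
    tt.to_csv(out / "tightness.tsv", sep="\t", index=False, float_format="%.10g")
    model.significance_.to_csv(out / "significance.tsv", sep="\t", index=False, float_format="%.10g")
    labels = partition_labels(model.partition_, model.tree_.labels)
    pd.DataFrame(
        {"observation_label": list(labels), "part_id": list(labels.values())}
    ).to_csv(out / "partition.tsv", sep="\t", index=False)
    model.null_samples_.to_frame().to_csv(
        out / "null_samples.tsv", sep="\t", index=False, float_format="%.10g"
    )

    import scipy
    import sklearn

    from . import __version__

    manifest = {
        "config": dataclasses.asdict(config),
        "input_sha256": _file_sha256(config.input),
        "n_leaves": model.tree_.n_leaves,
        "n_parts": model.n_parts_,
        "is_significant": model.is_significant_,
        "versions": {
            "tbest": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return model


def evaluate_to_report(
    partition_path: str | Path,
    truth_path: str | Path,
    merges_path: str | Path | None = None,
    enumeration_cap: int = 200_000,
    seed: int | None = 0,
) -> dict:
    """Compare a computed partition against a reference labeling.

    With a merge table the best branch partition of the tree is found and
    the relative cRI reported; without it only rand/cRI are computed.
    """
    part = read_labels(partition_path)
    truth = read_labels(truth_path)
    missing = sorted(set(part.index) ^ set(truth.index))
    if missing:
        raise ValueError(f"partition and truth cover different observations: {missing[:10]}")
    truth = truth.loc[part.index]
    report: dict = {
        "n_observations": int(part.size),
        "rand": rand_index(part.to_numpy(), truth.to_numpy()),
        "cri": corrected_rand(part.to_numpy(), truth.to_numpy()),
    }
    if merges_path is not None:
        merges = pd.read_csv(merges_path, sep="\t")
        tree = Dendrogram.from_merge_table(merges, labels=list(part.index))
        best, best_cri, exact = best_branch_partition(
            tree, truth.to_numpy(), enumeration_cap=enumeration_cap, seed=seed
        )
        best_labels = best.labels(tree.n_leaves)
        report.update(
            {
                "best_branch_cri": best_cri,
                "best_branch_exact": exact,
                "best_branch_parts": [tree.subtree_leaves(r).tolist() for r in best.part_roots],
                "relative_cri": relative_cri(part.to_numpy(), truth.to_numpy(), best_labels),
            }
        )
    return report
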