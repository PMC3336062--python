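"""Mid-level data fusion of two binned blocks.

Selected variables from each block are concatenated (block A first) on the
samples common to both blocks, re-autoscaled from the raw bin values, and
re-ranked by SVM-RFE so the joint model sees one reduced variable set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_selection import SelectionResult, loocv_select
from .preprocess import BinTable, Scaler, autoscale_fit_tolerant

__all__ = ["FusedDataset", "midlevel_fuse", "fuse_and_select"]

log = logging.getLogger("hmfuse")


@dataclass
class FusedDataset:
    """Concatenated selected variables on the common samples, with provenance.

    ``matrix`` holds raw (unscaled) bin values; ``scaler`` was fit on the
    training rows only.  ``column_indices`` locates each fused variable in
    the full concatenated [blockA bins | blockB bins] matrix.
    """

    matrix: np.ndarray
    sample_ids: list
    labels_: np.ndarray  # group label per row
    variable_names: list
    provenance: list  # dicts: block, bin_lo, bin_hi, source_column
    scaler: Scaler
    column_indices: np.ndarray
    row_indices: np.ndarray  # position of each row in blockA's sample order
    train_rows: np.ndarray | None = None

    def scaled(self, rows=None) -> np.ndarray:
        M = self.matrix if rows is None else self.matrix[rows]
        return self.scaler.transform(M)

    def write(self, csv_path, provenance_json_path=None) -> None:
        pd.DataFrame(
            self.matrix, index=self.sample_ids, columns=self.variable_names
        ).to_csv(csv_path, index_label="sample_id")
        if provenance_json_path is not None:
            with open(provenance_json_path, "w") as fh:
                json.dump(
                    {
                        "provenance": self.provenance,
                        "column_indices": [int(j) for j in self.column_indices],
                        "scaler_mean": self.scaler.mean_.tolist(),
                        "scaler_sd": self.scaler.sd_.tolist(),
                        "train_rows": None
                        if self.train_rows is None
                        else [int(i) for i in self.train_rows],
                    },
                    fh,
                    indent=1,
                )


def _selection_indices(sel) -> np.ndarray:
    if isinstance(sel, SelectionResult):
        return np.asarray(sel.selected, dtype=int)
    return np.asarray(sel, dtype=int)


def midlevel_fuse(
    blockA: BinTable, selA, blockB: BinTable, selB, train_rows=None
) -> FusedDataset:
    """Concatenate selected columns of two BinTables on their common samples.

    ``train_rows`` are positions in the common-sample order; the scaler is
    fit on those rows only (all rows when omitted).  Samples present in only
    one block are dropped with a logged count.
    """
    ia = _selection_indices(selA)
    ib = _selection_indices(selB)
    if ia.size == 0 and ib.size == 0:
        raise ValueError("empty selection on both blocks")
    if ia.size == 0 or ib.size == 0:
        log.warning("one block contributes no variables to the fusion")
    ids_a = list(blockA.values.index)
    ids_b_set = set(blockB.values.index)
    common = [s for s in ids_a if s in ids_b_set]
    if not common:
        raise ValueError("no common samples between the blocks")
    dropped = (len(ids_a) - len(common)) + (len(blockB.values) - len(common))
    if dropped:
        log.info("fusion dropped %d block-exclusive samples", dropped)
    A = blockA.values.loc[common].to_numpy()[:, ia] if ia.size else np.empty(
        (len(common), 0)
    )
    B = blockB.values.loc[common].to_numpy()[:, ib] if ib.size else np.empty(
        (len(common), 0)
    )
    matrix = np.hstack([A, B])
    n_a = blockA.values.shape[1]
    names, prov = [], []
    for j in ia:
        lo, hi = blockA.boundaries[j]
        names.append(f"{blockA.block_id}:{blockA.labels[j]}")
        prov.append(
            {"block": blockA.block_id, "bin_lo": lo, "bin_hi": hi,
             "source_column": int(j)}
        )
    for j in ib:
        lo, hi = blockB.boundaries[j]
        names.append(f"{blockB.block_id}:{blockB.labels[j]}")
        prov.append(
            {"block": blockB.block_id, "bin_lo": lo, "bin_hi": hi,
             "source_column": int(j)}
        )
    column_indices = np.concatenate([ia, n_a + ib]).astype(int)
    rows = train_rows if train_rows is not None else np.arange(len(common))
    rows = np.asarray(rows, dtype=int)
    _, scaler = autoscale_fit_tolerant(matrix[rows])
    groups = blockA.metadata.loc[common, "group"].to_numpy()
    pos_in_a = np.array([ids_a.index(s) for s in common], dtype=int)
    return FusedDataset(
        matrix=matrix,
        sample_ids=common,
        labels_=groups,
        variable_names=names,
        provenance=prov,
        scaler=scaler,
        column_indices=column_indices,
        row_indices=pos_in_a,
        train_rows=None if train_rows is None else rows,
    )


def fuse_and_select(
    blockA: BinTable,
    selA,
    blockB: BinTable,
    selB,
    labels,
    class_pair: tuple,
    train_rows=None,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[FusedDataset, SelectionResult]:
    """Fuse per-block selections, then re-rank the fused variables.

    ``labels`` are group labels aligned with the common-sample rows;
    selection runs on the training rows belonging to the two classes of
    ``class_pair``, autoscaled with the fused dataset's (training-row)
    scaler.
    """
    fused = midlevel_fuse(blockA, selA, blockB, selB, train_rows=train_rows)
    labels = np.asarray(labels)
    if labels.size != fused.matrix.shape[0]:
        raise ValueError("labels must align with the fused common-sample rows")
    ga, gb = class_pair
    rows = (
        np.asarray(train_rows, dtype=int)
        if train_rows is not None
        else np.arange(fused.matrix.shape[0])
    )
    pair_rows = rows[np.isin(labels[rows], [ga, gb])]
    y = np.where(labels[pair_rows] == gb, 1.0, -1.0)
    Xs = fused.scaler.transform(fused.matrix[pair_rows])
    sel = loocv_select(Xs, y, C=C, seed=seed, variable_names=fused.variable_names)
    return fused, sel
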