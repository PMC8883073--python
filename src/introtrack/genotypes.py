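"""Marker genotype matrix: the central observational object of the pipeline.

Each cell holds one of four codes describing the state of a line at a
diagnostic marker:

====  =========  =====================================
code  genotype   meaning
====  =========  =====================================
A     ArAr       homozygous donor (B. rapa)
B     AjAj       homozygous recipient (B. juncea A)
H     ArAj       heterozygous
D     --         missing call
====  =========  =====================================

Markers are ordered by chromosome and physical position, mirroring the
graphical-genotype convention of arranging markers along the chromosomes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODES = ("A", "B", "H", "D")
MISSING = "D"

# graphical-genotype palette: donor orange, recipient blue, het green, missing grey
DEFAULT_PALETTE = {"A": "#E69F00", "B": "#3B6FB6", "H": "#4DAF4A", "D": "#BDBDBD"}

__all__ = [
    "CODES",
    "MISSING",
    "MarkerGenotypeMatrix",
    "load_matrix",
    "fill_missing",
    "per_line_summary",
    "export_graphical_genotypes",
]


class MarkerGenotypeMatrix:
    """Lines x ordered markers of genotype calls, plus per-line recipient labels.

    Parameters
    ----------
    calls :
        DataFrame indexed by line id, columns are marker ids, values in
        ``{"A", "B", "H", "D"}``.
    markers :
        DataFrame indexed by marker id with columns ``chrom`` and ``bp``
        (optionally ``cM``).  Must cover every column of ``calls``.
    recipients :
        Series mapping line id -> recipient parent label.
    """

    def __init__(self, calls: pd.DataFrame, markers: pd.DataFrame, recipients: pd.Series):
        if calls.index.duplicated().any():
            raise ValueError(f"duplicate line ids: {calls.index[calls.index.duplicated()].tolist()}")
        missing_meta = [m for m in calls.columns if m not in markers.index]
        if missing_meta:
            raise ValueError(f"markers without metadata: {missing_meta}")
        markers = markers.loc[list(calls.columns)]
        bad = ~calls.isin(CODES)
        if bad.to_numpy().any():
            rows, cols = np.nonzero(bad.to_numpy())
            coords = [(calls.index[r], calls.columns[c], calls.iat[r, c]) for r, c in zip(rows, cols)][:5]
            raise ValueError(f"invalid genotype codes (line, marker, code): {coords}")
        # enforce chromosome-major, bp-increasing marker order
        order = markers.sort_values(["chrom", "bp"], kind="stable").index
        if list(order) != list(calls.columns):
            logger.warning("markers were not sorted by chromosome and bp; auto-sorting")
            calls = calls[list(order)]
            markers = markers.loc[list(order)]
        if recipients.reindex(calls.index).isna().any():
            missing = recipients.reindex(calls.index)
            raise ValueError(f"lines without recipient label: {missing[missing.isna()].index.tolist()}")
        self.calls = calls
        self.markers = markers
        self.recipients = recipients.reindex(calls.index)

    # ------------------------------------------------------------------ basic
    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    @property
    def n_calls(self) -> int:
        return self.calls.size

    def counts(self) -> dict[str, int]:
        """Whole-matrix genotype counts keyed by code."""
        flat = self.calls.to_numpy().ravel()
        return {c: int((flat == c).sum()) for c in CODES}

    def copy(self) -> "MarkerGenotypeMatrix":
        return MarkerGenotypeMatrix(self.calls.copy(), self.markers.copy(), self.recipients.copy())

    # ------------------------------------------------------------------- I/O
    def save(self, path, markers_path=None, header_comment: str | None = None) -> None:
        """Write the matrix CSV (line_id, recipient, marker columns).

        When ``markers_path`` is given, marker metadata (chrom, bp, cM) is
        written alongside as TSV so the matrix round-trips exactly.
        """
        out = self.calls.copy()
        out.insert(0, "recipient", self.recipients)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, index_label="line_id")
        if markers_path is not None:
            self.markers.to_csv(markers_path, sep="\t", index_label="marker_id")


def load_matrix(path, markers_path=None) -> MarkerGenotypeMatrix:
    """Load a genotype-matrix CSV written by :meth:`MarkerGenotypeMatrix.save`.

    Without a marker metadata table, chromosome and position are inferred
    from marker ids of the form ``<chrom>_<index>`` (the index, derived from
    the bp position, preserves physical order).
    """
    df = pd.read_csv(path, comment="#", dtype=str).set_index("line_id")
    df.index.name = None
    recipients = df.pop("recipient").rename(None)
    if markers_path is not None:
        markers = pd.read_csv(markers_path, sep="\t", comment="#").set_index("marker_id")
    else:
        parts = [m.rsplit("_", 1) for m in df.columns]
        try:
            markers = pd.DataFrame(
                {"chrom": [p[0] for p in parts], "bp": [int(p[1]) for p in parts]},
                index=df.columns,
            )
        except (IndexError, ValueError) as err:
            raise ValueError(
                "marker ids are not of the form <chrom>_<index>; "
                "pass a marker metadata table"
            ) from err
    return MarkerGenotypeMatrix(df, markers, recipients)


def fill_missing(matrix: MarkerGenotypeMatrix) -> MarkerGenotypeMatrix:
    """Replace each missing call by its nearest non-missing neighbour.

    Per line and per chromosome, every ``D`` takes the call of the closest
    non-missing marker in bp on the same chromosome; an exact distance tie
    goes to the left (smaller bp) neighbour.  A chromosome with no
    non-missing call for a line stays missing.  The input is not modified.
    """
    calls = matrix.calls.copy()
    markers = matrix.markers
    for chrom, sub in markers.groupby("chrom", sort=False):
        cols = list(sub.index)
        bp = sub["bp"].to_numpy(dtype=np.int64)
        block = calls[cols].to_numpy()
        for i in range(block.shape[0]):
            row = block[i]
            miss = row == MISSING
            if not miss.any() or miss.all():
                continue
            obs_idx = np.nonzero(~miss)[0]
            obs_bp = bp[obs_idx]
            for j in np.nonzero(miss)[0]:
                k = np.searchsorted(obs_bp, bp[j])
                if k == 0:
                    pick = obs_idx[0]
                elif k == len(obs_bp):
                    pick = obs_idx[-1]
                else:
                    dl = bp[j] - obs_bp[k - 1]
                    dr = obs_bp[k] - bp[j]
                    pick = obs_idx[k - 1] if dl <= dr else obs_idx[k]
                row[j] = block[i, pick]
        calls[cols] = block
    return MarkerGenotypeMatrix(calls, matrix.markers.copy(), matrix.recipients.copy())


def per_line_summary(matrix: MarkerGenotypeMatrix) -> pd.DataFrame:
    """Per-line proportions of A, B and H over non-missing calls.

    Returns a DataFrame indexed by line id with columns ``n_A``, ``n_B``,
    ``n_H``, ``n_D``, ``prop_A``, ``prop_B``, ``prop_H`` (proportions of the
    non-missing denominator; NaN and ``undefined=True`` when a line has no
    non-missing call) and the line's recipient label.  Group-wise means by
    recipient are available via ``result.groupby("recipient").mean()``.
    """
    arr = matrix.calls.to_numpy()
    out = pd.DataFrame(index=matrix.calls.index)
    for c in CODES:
        out[f"n_{c}"] = (arr == c).sum(axis=1)
    denom = out[["n_A", "n_B", "n_H"]].sum(axis=1)
    for c in ("A", "B", "H"):
        with np.errstate(invalid="ignore"):
            out[f"prop_{c}"] = np.where(denom > 0, out[f"n_{c}"] / denom.replace(0, np.nan), np.nan)
    out["undefined"] = denom == 0
    out["recipient"] = matrix.recipients
    return out


def group_summary(summary: pd.DataFrame, by: str = "recipient") -> pd.DataFrame:
    """Mean genotype proportions per recipient (or other label) group."""
    return summary.groupby(by)[["prop_A", "prop_B", "prop_H"]].mean()


def export_graphical_genotypes(matrix: MarkerGenotypeMatrix, path=None, palette=None,
                               figsize=None):
    """Render the lines x markers tile plot (graphical genotypes).

    Donor-homozygous cells are orange, recipient blue, heterozygous green,
    missing grey, matching the conventional colouring of introgression
    graphical genotypes.  Returns the matplotlib figure; saves to ``path``
    when given.  Layout is deterministic for fixed input.
    """
    import matplotlib
    matplotlib.use("Agg")  # headless-safe; must precede pyplot import
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    palette = palette or DEFAULT_PALETTE
    code_to_int = {c: i for i, c in enumerate(CODES)}
    img = np.vectorize(code_to_int.__getitem__)(matrix.calls.to_numpy())
    n_lines, n_markers = img.shape
    if figsize is None:
        figsize = (max(4.0, n_markers * 0.08), max(2.0, n_lines * 0.06))
    fig, ax = plt.subplots(figsize=figsize)
    cmap = ListedColormap([palette[c] for c in CODES])
    ax.imshow(img, aspect="auto", interpolation="none", cmap=cmap, vmin=0, vmax=3)
    ax.set_xlabel("markers (chromosome-ordered)")
    ax.set_ylabel("lines")
    # chromosome boundaries
    chroms = matrix.markers["chrom"].to_numpy()
    bounds = np.nonzero(chroms[1:] != chroms[:-1])[0]
    for b in bounds:
        ax.axvline(b + 0.5, color="black", lw=0.5)
    ax.legend(handles=[Patch(color=palette[c], label=c) for c in CODES],
              loc="upper left", bbox_to_anchor=(1.01, 1), frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
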