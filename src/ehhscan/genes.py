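"""Gene-interval annotation of candidate SNPs.

A light replacement for full consequence annotation: a SNP inside a gene
interval is labeled intragenic with that gene's name; otherwise the
nearest genes within a flank on each side are reported as intergenic
context with their distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = ["GeneModel", "annotate"]


@dataclass
class GeneModel:
    """Gene intervals (1-based closed) with containment/nearest lookup."""

    frame: pd.DataFrame  # chrom, start, end, name, strand
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.frame["start"] > self.frame["end"]).any():
            raise ValueError("gene interval with start > end")
        names = self.frame["name"]
        if names.duplicated().any():
            # disambiguate duplicated names by position
            self.frame = self.frame.copy()
            dup = self.frame["name"].duplicated(keep=False)
            self.frame.loc[dup, "name"] = [
                f"{n}@{s}" for n, s in zip(
                    self.frame.loc[dup, "name"], self.frame.loc[dup, "start"]
                )
            ]
        for chrom, grp in self.frame.groupby("chrom"):
            tree = IntervalTree()
            for r in grp.itertuples():
                tree[r.start:r.end + 1] = r.name  # closed -> half-open
            self._trees[str(chrom)] = tree

    @classmethod
    def from_bed(cls, path) -> "GeneModel":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                p = line.split("\t")
                rows.append(
                    {
                        "chrom": p[0], "start": int(p[1]) + 1, "end": int(p[2]),
                        "name": p[3] if len(p) > 3 else f"{p[0]}:{p[1]}-{p[2]}",
                        "strand": p[5] if len(p) > 5 else ".",
                    }
                )
        return cls(frame=pd.DataFrame(rows))

    def overlapping(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(str(chrom))
        return sorted(iv.data for iv in tree[pos]) if tree is not None else []

    def nearest(self, chrom: str, pos: int, flank_bp: int) -> list[tuple[str, int, str]]:
        """Nearest non-overlapping gene within the flank on each side."""
        grp = self.frame[self.frame["chrom"].astype(str) == str(chrom)]
        best = {"left": None, "right": None}
        for r in grp.itertuples():
            if r.start <= pos <= r.end:
                continue
            if r.end < pos:
                d = pos - r.end
                if d <= flank_bp and (best["left"] is None or d < best["left"][1]):
                    best["left"] = (r.name, d)
            else:
                d = r.start - pos
                if d <= flank_bp and (best["right"] is None or d < best["right"][1]):
                    best["right"] = (r.name, d)
        return [
            (v[0], v[1], side) for side, v in best.items() if v is not None
        ]


def annotate(
    snps: pd.DataFrame, genes: GeneModel | None, flank_bp: int = 500_000
) -> pd.DataFrame:
    """Gene labels for SNP positions (columns chrom, pos required).

    Returns the input with ``genes`` and ``consequence`` columns added:
    intragenic SNPs get the containing gene name(s), intergenic ones the
    nearest genes within the flank with distances, otherwise
    'unannotated'.
    """
    out = snps.copy()
    labels, kinds = [], []
    for r in out.itertuples():
        if genes is None or genes.frame.empty:
            labels.append("")
            kinds.append("unannotated")
            continue
        inside = genes.overlapping(str(r.chrom), int(r.pos))
        if inside:
            labels.append(";".join(inside))
            kinds.append("intragenic")
            continue
        near = genes.nearest(str(r.chrom), int(r.pos), flank_bp)
        if near:
            labels.append(
                ";".join(f"{name}({dist}bp {side})" for name, dist, side in near)
            )
            kinds.append("intergenic")
        else:
            labels.append("")
            kinds.append("unannotated")
    out["genes"] = labels
    out["consequence"] = kinds
    return out
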