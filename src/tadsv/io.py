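"""Plain-text readers and writers for all pipeline inputs and outputs.

Coordinates are 0-based half-open (BED dialect) throughout.  Contact matrices
travel as COO text (bin1_index, bin2_index, value) plus a bin-table BED
(chrom, start, end, bin_index); boundaries as BED6 with the source in the
name column and strength x 1000 in the score column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import LADTrack
from .expression import GeneRecord
from .hic import Boundary, BoundarySet, ContactMatrix, NormalizationVector
from .sv import SVEvent

log = logging.getLogger(__name__)


# -- contact matrices -------------------------------------------------------

def write_contact_matrix(mat: ContactMatrix, coo_path, bins_path) -> None:
    n = mat.n_bins
    with open(bins_path, "w") as fh:
        for i in range(n):
            fh.write(f"{mat.chrom}\t{i * mat.bin_size}\t{(i + 1) * mat.bin_size}\t{i}\n")
    iu = np.triu_indices(n)
    vals = mat.values[iu]
    ok = np.isfinite(vals) & (vals != 0)
    with open(coo_path, "w") as fh:
        for i, j, v in zip(iu[0][ok], iu[1][ok], vals[ok]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def read_contact_matrix(coo_path, bins_path,
                        mask: np.ndarray | None = None) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "idx"])
    chroms = bins["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("bin table must cover exactly one chromosome")
    bin_size = int((bins["end"] - bins["start"]).iloc[0])
    n = len(bins)
    values = np.zeros((n, n))
    coo = pd.read_csv(coo_path, sep="\t", header=None,
                      names=["b1", "b2", "value"])
    values[coo["b1"], coo["b2"]] = coo["value"]
    values[coo["b2"], coo["b1"]] = coo["value"]
    m = ContactMatrix(str(chroms[0]), bin_size, values, mask)
    return m.with_auto_mask() if mask is None else m


def write_norm_vector(nv: NormalizationVector, path) -> None:
    pd.Series(nv.scores).to_csv(path, sep="\t", header=False)


def read_norm_vector(path, chrom: str) -> NormalizationVector:
    s = pd.read_csv(path, sep="\t", header=None, index_col=0)[1]
    return NormalizationVector(chrom, s.to_numpy())


# -- boundaries -------------------------------------------------------------

def write_boundaries_bed(bset: BoundarySet, path) -> None:
    with open(path, "w") as fh:
        for b in bset:
            score = int(round(b.strength * 1000))
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t"
                     f"{b.source or '.'}\t{score}\t.\n")


def read_boundaries_bed(path) -> BoundarySet:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strength = float(f[4]) / 1000 if len(f) > 4 else 0.0
            source = f[3] if len(f) > 3 and f[3] != "." else ""
            out.append(Boundary(f[0], int(f[1]), int(f[2]), strength, source))
    return BoundarySet(out)


# -- SVs --------------------------------------------------------------------

SV_COLUMNS = ["chrom", "start", "end", "sample_id", "cohort", "sv_type",
              "origin"]


def write_svs(svs: Sequence[SVEvent], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.sample_id, s.cohort, s.sv_type, s.origin)
         for s in svs], columns=SV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_svs(path) -> list[SVEvent]:
    """Read SV records; inter-chromosomal rows (chrom2 column differing) are
    dropped with a logged count."""
    df = pd.read_csv(path, sep="\t")
    dropped = 0
    if "chrom2" in df.columns:
        inter = df["chrom2"].notna() & (df["chrom2"] != df["chrom"])
        dropped = int(inter.sum())
        df = df[~inter]
    if dropped:
        log.info("dropped %d inter-chromosomal SV records", dropped)
    return [SVEvent(r.sample_id, r.cohort, r.chrom, int(r.start), int(r.end),
                    r.sv_type, getattr(r, "origin", "somatic"))
            for r in df.itertuples(index=False)]


# -- annotation tracks ------------------------------------------------------

def write_state_track(track: Sequence[tuple[str, int, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, st in track:
            fh.write(f"{chrom}\t{s}\t{e}\t{st}\n")


def read_state_track(path) -> list[tuple[str, int, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                f = line.split("\t")
                out.append((f[0], int(f[1]), int(f[2]), int(f[3])))
    return out


def write_lad_track(track: LADTrack, path) -> None:
    with open(path, "w") as fh:
        for label, ivs in (("LAD", track.lads), ("interLAD", track.inter_lads)):
            for chrom, pairs in ivs.items():
                for s, e in pairs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def read_lad_track(path) -> LADTrack:
    lads: dict[str, list] = {}
    inter: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, label = line.split("\t")[:4]
            tgt = lads if label.strip() == "LAD" else inter
            tgt.setdefault(chrom, []).append((int(s), int(e)))
    return LADTrack(lads, inter)


def write_genes_bed(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[GeneRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                f = line.rstrip("\n").split("\t")
                out.append(GeneRecord(f[3], f[0], int(f[1]), int(f[2]),
                                      f[5] if len(f) > 5 else "+"))
    return out


# -- tables -----------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, s in chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, s = line.split("\t")[:2]
                out[c] = int(s)
    return out
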