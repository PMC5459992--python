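"""Readers and writers for the pipeline's on-disk formats.

Coverage tables are bismark-style TSVs, one per sample, with columns
(chrom, start, end, percent methylation, count methylated,
count unmethylated).  Starts are treated as 1-based on read by default
(``coord_base=1``, matching common exports) and converted once to the
package's internal 0-based convention; BED outputs are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .methylome import GeneModel, MethylMatrix

COVERAGE_COLUMNS = ["chrom", "start", "end", "pct_meth", "count_meth", "count_unmeth"]


def read_coverage_table(path, coord_base: int = 1) -> pd.DataFrame:
    """One sample's coverage TSV -> DataFrame (chrom, pos, count_meth, count_total)."""
    if coord_base not in (0, 1):
        raise FormatError("coord_base must be 0 or 1")
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=COVERAGE_COLUMNS)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as coverage TSV ({exc})") from exc
    if df[["count_meth", "count_unmeth"]].lt(0).any().any():
        bad = int(df.index[(df[["count_meth", "count_unmeth"]] < 0).any(axis=1)][0])
        raise FormatError(f"{path}: negative count at line {bad + 1}")
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        raise FormatError(f"{path}: duplicated site at line {int(df.index[dup][0]) + 1}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(np.int64) - coord_base,
            "count_meth": df["count_meth"].astype(np.int64),
            "count_total": (df["count_meth"] + df["count_unmeth"]).astype(np.int64),
        }
    )
    return out


def read_coverage_tables(paths: dict, metadata: pd.DataFrame, coord_base: int = 1) -> MethylMatrix:
    """Assemble per-sample coverage TSVs into a MethylMatrix.

    ``paths`` maps sample_id -> file path; ``metadata`` needs columns
    (sample_id, generation, phenotype) covering every sample.  The site list
    is the union across samples; a sample missing a site gets coverage 0.
    """
    meta = metadata.set_index("sample_id")
    missing = set(paths) - set(meta.index)
    if missing:
        raise FormatError(f"metadata missing samples: {sorted(missing)}")
    tables = {sid: read_coverage_table(p, coord_base) for sid, p in paths.items()}
    all_sites = (
        pd.concat([t[["chrom", "pos"]] for t in tables.values()])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(all_sites)
    sample_ids = list(paths)
    meth = np.zeros((len(all_sites), len(sample_ids)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, sid in enumerate(sample_ids):
        t = tables[sid].set_index(["chrom", "pos"])
        idx = key.get_indexer(t.index)
        meth[idx, j] = t["count_meth"].to_numpy()
        total[idx, j] = t["count_total"].to_numpy()
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "generation": meta.loc[sample_ids, "generation"].to_numpy(),
            "phenotype": meta.loc[sample_ids, "phenotype"].to_numpy(),
        }
    )
    return MethylMatrix(all_sites, meth, total, samples)


def write_coverage_tables(m: MethylMatrix, out_dir, coord_base: int = 1) -> dict:
    """Write one bismark-style coverage TSV per sample; returns sample_id -> path.

    Only covered (total > 0) sites are written, as in real exports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for j, sid in enumerate(m.samples["sample_id"]):
        covered = m.total[:, j] > 0
        cm = m.meth[covered, j]
        ct = m.total[covered, j]
        df = pd.DataFrame(
            {
                "chrom": m.sites.loc[covered, "chrom"].to_numpy(),
                "start": m.sites.loc[covered, "pos"].to_numpy() + coord_base,
                "end": m.sites.loc[covered, "pos"].to_numpy() + coord_base,
                "pct_meth": np.round(100.0 * cm / ct, 6),
                "count_meth": cm,
                "count_unmeth": ct - cm,
            }
        )
        path = out_dir / f"{sid}.cov.tsv"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[sid] = path
    m.samples.to_csv(out_dir / "samples.csv", index=False)
    return paths


def read_bed12(path) -> GeneModel:
    """BED12 -> GeneModel (0-based half-open; strand-aware TSS derived)."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    rows = []
    for r in df.itertuples():
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(r.block_count) or len(starts) != int(r.block_count):
            raise FormatError(f"{path}: block count mismatch for {r.name}")
        ex_s = [int(r.start) + s for s in starts]
        ex_e = [a + b for a, b in zip(ex_s, sizes)]
        if ex_s[0] < r.start or ex_e[-1] > r.end:
            raise FormatError(f"{path}: exon blocks outside gene span for {r.name}")
        rows.append(
            {
                "gene_id": str(r.name),
                "chrom": str(r.chrom),
                "strand": str(r.strand),
                "start": int(r.start),
                "end": int(r.end),
                "exon_starts": ex_s,
                "exon_ends": ex_e,
            }
        )
    return GeneModel(pd.DataFrame(rows))


def write_bed12(gm: GeneModel, path) -> None:
    rows = []
    for g in gm.genes.itertuples():
        sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
        starts = ",".join(str(s - g.start) for s in g.exon_starts)
        rows.append(
            f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
            f"\t{g.start}\t{g.end}\t0\t{len(g.exon_starts)}\t{sizes}\t{starts}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_sites_bed(sites: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Site list -> BED (0-based half-open single-base intervals)."""
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
        }
    )
    if name_col and name_col in sites:
        df["name"] = sites[name_col]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None).iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return pd.DataFrame({"chrom": df["chrom"].astype(str), "pos": df["start"].astype(np.int64)})


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene_id", "fold_change", "p_value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: DE table needs columns {sorted(required)}")
    return df


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
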