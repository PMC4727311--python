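"""Tab-separated file dialects shared by all stages.

Genotype TSV: rows = individuals/inbreds, columns = markers, values allele
dosage (0/1/2, founders 0/2) with ``NA`` for missing; first column is the
individual id.  Map TSV: marker_id, chromosome, pos_bp (1-based), pos_cm.
``write . read`` is the identity on valid files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneticMap
from .founders import FounderPanel

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_founder_panel",
    "write_founder_panel",
    "write_phenotypes",
    "write_scan",
    "write_power",
    "founder_panel_from_vcf",
]

_NA = "NA"


def write_genotypes(path, genotypes: np.ndarray, ids, marker_ids) -> None:
    df = pd.DataFrame(np.asarray(genotypes), index=list(ids), columns=list(marker_ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep=_NA)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    if df.empty:
        raise ValueError(f"{path}: empty genotype matrix")
    return df


def write_map(path, gmap: GeneticMap) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "marker_id" not in df.columns:
        raise ValueError(f"{path}: map file needs a marker_id column")
    return GeneticMap(df)  # sorts; unsorted input is normalised


def write_founder_panel(prefix, panel: FounderPanel) -> None:
    prefix = Path(prefix)
    write_genotypes(prefix.with_suffix(".geno.tsv"), panel.genotypes, panel.ids, panel.gmap.marker_ids)
    write_map(prefix.with_suffix(".map.tsv"), panel.gmap)
    meta = pd.DataFrame({"id": panel.ids, "panel": panel.panel_label})
    meta.to_csv(prefix.with_suffix(".panels.tsv"), sep="\t", index=False)


def read_founder_panel(geno_path, map_path, panels_path=None, common_parent_id=None) -> FounderPanel:
    geno = read_genotypes(geno_path)
    gmap = read_map(map_path)
    order = [m for m in gmap.marker_ids if m in set(geno.columns)]
    if len(order) != gmap.n_markers:
        missing = set(gmap.marker_ids) - set(geno.columns)
        raise ValueError(f"markers in map but not in genotypes: {sorted(missing)[:5]} ...")
    geno = geno[order]
    if panels_path is not None:
        meta = pd.read_csv(panels_path, sep="\t").set_index("id")
        labels = meta.loc[geno.index, "panel"].to_numpy(object)
        common = geno.index[labels == "common"]
        cp = str(common[0]) if len(common) else None
    else:
        labels = np.array(["panel1"] * len(geno), object)
        cp = common_parent_id
        if cp is None or cp not in geno.index:
            raise ValueError("common_parent_id must name a row of the genotype matrix")
        labels[list(geno.index).index(cp)] = "common"
    return FounderPanel(
        genotypes=geno.to_numpy(float),
        ids=[str(i) for i in geno.index],
        panel_label=labels,
        common_parent_id=cp,
        gmap=gmap,
    )


def write_phenotypes(path, ids, genotypic_values, phenotypes) -> None:
    pd.DataFrame(
        {"individual_id": list(ids), "genotypic_value": genotypic_values, "phenotype": phenotypes}
    ).to_csv(path, sep="\t", index=False)


def write_scan(path, result) -> None:
    tab = result.table.drop(columns=["effects_by_subpop"]).copy()
    tab.insert(3, "model_id", result.model_id)
    tab.to_csv(path, sep="\t", index=False)


def write_power(path, power_df: pd.DataFrame, scenario_id: str = "") -> None:
    out = power_df.copy()
    if scenario_id:
        out.insert(0, "scenario_id", scenario_id)
    out.to_csv(path, sep="\t", index=False)


def write_ld_report(path, pairs: pd.DataFrame, fit, n_bins: int = 50) -> None:
    """Binned LD-decay table: distance_bin, mean_r2, n_pairs, fitted_r2."""
    edges = np.linspace(0.0, pairs["distance"].max(), n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(pairs["distance"], edges) - 1, 0, n_bins - 1)
    grouped = pairs.groupby(idx)["r2"]
    out = pd.DataFrame(
        {
            "distance_bin": mid[grouped.mean().index],
            "mean_r2": grouped.mean().to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        }
    )
    out["fitted_r2"] = fit.curve(out["distance_bin"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


def write_ld_fit(path, fit) -> None:
    pd.DataFrame(
        [{"k": fit.k, "n": fit.n, "distance_at_r2_0_1": fit.distance_at_r2_0_1,
          "crossed": fit.crossed}]
    ).to_csv(path, sep="\t", index=False)


def write_pcoa(path, coords: pd.DataFrame, proportions) -> None:
    out = coords.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")
    # variance proportions on a trailing comment-style row would break the
    # dialect; they go in a sidecar file
    pd.DataFrame({"axis": coords.columns, "proportion": proportions}).to_csv(
        str(path) + ".variance.tsv", sep="\t", index=False
    )


def founder_panel_from_vcf(vcf_path, panels_path=None, common_parent_id=None) -> FounderPanel:
    """Import biallelic SNPs with homozygous calls from a VCF.

    Heterozygous founder calls and multi-allelic sites are rejected with the
    offending site named (founders must be inbred).  Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(vcf_path))
    ids = list(vcf.samples)
    rows, markers = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic site {var.CHROM}:{var.POS}")
        g = np.array(var.gt_types, dtype=float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        if (g == 1).any():
            raise ValueError(f"heterozygous founder call at {var.CHROM}:{var.POS}")
        dos = np.where(g == 0, 0.0, np.where(g == 3, 2.0, np.nan))
        rows.append(dos)
        markers.append((var.ID or f"{var.CHROM}_{var.POS}", str(var.CHROM), int(var.POS)))
    if not rows:
        raise ValueError("no variants in VCF")
    gmap = GeneticMap(pd.DataFrame(markers, columns=["marker_id", "chromosome", "pos_bp"]))
    geno = np.stack(rows, axis=1)
    labels = np.array(["panel1"] * len(ids), object)
    if common_parent_id is None or common_parent_id not in ids:
        raise ValueError("common_parent_id must name a VCF sample")
    labels[ids.index(common_parent_id)] = "common"
    if panels_path is not None:
        meta = pd.read_csv(panels_path, sep="\t").set_index("id")
        labels = meta.loc[ids, "panel"].to_numpy(object)
    return FounderPanel(
        genotypes=geno, ids=ids, panel_label=labels, common_parent_id=common_parent_id, gmap=gmap
    )
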