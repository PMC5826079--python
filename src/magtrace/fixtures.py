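"""Loader for the bundled example dataset (see ``data/MANIFEST.md``)."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import dendropy
import pandas as pd

from magtrace.bin_confidence import BinQuality, GeneSet
from magtrace.errors import InputError
from magtrace.tree_ops import parse_newick

# The six-gene phototrophy set (reaction center + early bacteriochlorophyll
# synthesis) and the five late bacteriochlorophyll synthesis genes used in the
# worked absence calculations.
PHOTOTROPHY_SET = GeneSet(
    "phototrophy_rc", ("pufL", "pufM", "pufC", "bchX", "bchY", "bchZ")
)
BCH_SET = GeneSet("bch_synthesis", ("bchL", "bchN", "bchB", "bchM", "bchE"))

METAGENOME_BINS = (
    "CP1_1M",
    "CP2_2F",
    "CP2_20G",
    "CP2_42A",
    "JP1_8",
    "JP1_16",
    "JP1_20",
    "JP1_191",
    "JP3_7",
    "JP3_13",
)
ISOLATE = "Kouleothrix_aurantiaca"

RC_MARKER = "Type 2 reaction center"


def _data_path(name: str):
    return resources.files("magtrace").joinpath("data", name)


@dataclass(frozen=True)
class FixtureBundle:
    bin_quality: dict[str, BinQuality]
    bin_table: pd.DataFrame
    marker_matrix: pd.DataFrame
    fusion_states: dict[str, int]
    phototrophs: tuple[str, ...]
    _organismal_newick: str
    _rc_newick: dict[str, str]

    def organismal_tree(self) -> dendropy.Tree:
        return parse_newick(self._organismal_newick)

    def rc_tree(self, variant: str = "a") -> dendropy.Tree:
        if variant not in self._rc_newick:
            raise InputError(f"unknown reaction-center tree variant {variant!r}")
        return parse_newick(self._rc_newick[variant])

    def marker_cell(self, bin_id: str, marker: str) -> str:
        return str(self.marker_matrix.loc[bin_id, marker])

    def is_present(self, bin_id: str, marker: str) -> bool:
        cell = self.marker_cell(bin_id, marker)
        return cell.startswith("+") or (cell not in ("-", "") and cell != "nan")


def load_bundle() -> FixtureBundle:
    bins_df = pd.read_csv(_data_path("bin_quality.tsv"), sep="\t")
    quality = {
        str(r.bin_id): BinQuality.from_percent(
            str(r.bin_id),
            int(r.n_cds),
            float(r.completeness_pct),
            float(r.contamination_pct),
            float(r.strain_het_pct),
        )
        for r in bins_df.itertuples()
    }
    matrix = pd.read_csv(
        _data_path("marker_matrix.tsv"), sep="\t", index_col="bin_id"
    )
    fusion_df = pd.read_csv(_data_path("fusion_states.tsv"), sep="\t")
    fusion = {str(r.leaf): int(r.fused) for r in fusion_df.itertuples()}
    with _data_path("phototrophs.txt").open() as fh:
        phototrophs = tuple(l.strip() for l in fh if l.strip())
    with _data_path("organismal.nwk").open() as fh:
        org = fh.read()
    rc = {}
    for variant in ("a", "b"):
        with _data_path(f"rc_gene_variant_{variant}.nwk").open() as fh:
            rc[variant] = fh.read()
    return FixtureBundle(
        bin_quality=quality,
        bin_table=bins_df,
        marker_matrix=matrix,
        fusion_states=fusion,
        phototrophs=phototrophs,
        _organismal_newick=org,
        _rc_newick=rc,
    )
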