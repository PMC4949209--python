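"""Plain-text readers and writers for genotype, map and phenotype tables.

Native genotype format: tab-separated matrix with header
``genotype_id<TAB>subpop<TAB><marker ids...>`` and dosage calls coded
0/1/2 with ``NA`` for missing. The companion map file is tab-separated
``marker<TAB>chromosome<TAB>cM``. A simple HapMap-like dialect
(``rs  alleles  chrom  pos`` then two-letter diplotypes, ``NN`` missing)
is also accepted; dosages count the alphabetically-second allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, validate_phenotypes

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
_VALID = {"0": 0.0, "1": 1.0, "2": 2.0}


class FormatError(PanelError):
    """Malformed input file."""


def read_map(map_path) -> pd.DataFrame:
    mm = pd.read_csv(map_path, sep="\t", dtype={0: str, 1: str})
    if len(mm.columns) < 3:
        raise FormatError(f"map file {map_path} needs 3 columns, got {len(mm.columns)}")
    mm.columns = ["marker", "chromosome", "cM", *mm.columns[3:]]
    mm["cM"] = mm["cM"].astype(float)
    return mm[["marker", "chromosome", "cM"]]


def read_genotypes(matrix_path, map_path) -> GenotypePanel:
    """Read the native dosage matrix + map into a :class:`GenotypePanel`.

    Unknown call tokens become missing; the number of such tokens is
    logged and stored on the returned panel as ``n_unknown_tokens``.
    Markers present in the matrix but absent from the map raise a
    :class:`FormatError` naming the first offender.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.columns[0] != "genotype_id" or raw.columns[1] != "subpop":
        raise FormatError(
            f"{matrix_path}: expected header starting 'genotype_id\\tsubpop'"
        )
    markers = list(raw.columns[2:])
    mm = read_map(map_path)
    mapped = set(mm["marker"])
    for m in markers:
        if m not in mapped:
            raise FormatError(f"marker {m!r} in {matrix_path} has no map entry")
    mm = mm.set_index("marker").loc[markers].reset_index()

    calls = raw[markers].to_numpy(dtype=str)
    dosage = np.full(calls.shape, np.nan)
    unknown = 0
    for tok, val in _VALID.items():
        dosage[calls == tok] = val
    known = np.isin(calls, list(_VALID) + [MISSING_TOKEN, "nan"])
    unknown = int((~known).sum())
    if unknown:
        log.warning("%d unknown genotype tokens set to missing", unknown)
    panel = GenotypePanel(
        raw["genotype_id"].tolist(), raw["subpop"].tolist(), dosage, mm
    )
    panel.n_unknown_tokens = unknown
    return panel


def write_genotypes(panel: GenotypePanel, matrix_path, map_path) -> None:
    """Write the native matrix + map; inverse of :func:`read_genotypes`."""
    with open(matrix_path, "w") as fh:
        fh.write("genotype_id\tsubpop\t" + "\t".join(panel.marker_ids) + "\n")
        for i, gid in enumerate(panel.genotype_ids):
            row = panel.dosage[i]
            calls = [
                MISSING_TOKEN if np.isnan(v) else str(int(v)) for v in row
            ]
            fh.write(f"{gid}\t{panel.subpops[i]}\t" + "\t".join(calls) + "\n")
    write_map(panel.marker_map, map_path)


def write_map(marker_map: pd.DataFrame, map_path) -> None:
    with open(map_path, "w") as fh:
        fh.write("marker\tchromosome\tcM\n")
        for _, r in marker_map.iterrows():
            fh.write(f"{r['marker']}\t{r['chromosome']}\t{r['cM']:g}\n")


def read_hapmap(path, map_path=None) -> GenotypePanel:
    """Read a HapMap-like dialect: rs, alleles, chrom, pos, then diplotypes.

    Dosage counts the alphabetically-second allele of the ``alleles``
    column (e.g. for ``A/G``, ``GG`` -> 2, ``AG`` -> 1). ``NN`` or ``--``
    are missing; any other token is missing with a logged count.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    need = ["rs", "alleles", "chrom", "pos"]
    if list(raw.columns[:4]) != need:
        raise FormatError(f"{path}: expected columns {need}, got {list(raw.columns[:4])}")
    gids = list(raw.columns[4:])
    n_m = len(raw)
    dosage = np.full((len(gids), n_m), np.nan)
    alleles = {}
    unknown = 0
    for j, row in raw.iterrows():
        a, b = sorted(str(row["alleles"]).split("/")[:2])
        alleles[row["rs"]] = (a, b)
        lut = {a + a: 0.0, a + b: 1.0, b + a: 1.0, b + b: 2.0}
        for i, g in enumerate(gids):
            tok = str(row[g])
            if tok in lut:
                dosage[i, j] = lut[tok]
            elif tok not in ("NN", "--", "nan"):
                unknown += 1
    if unknown:
        log.warning("%d unknown diplotype tokens set to missing", unknown)
    mm = pd.DataFrame(
        {"marker": raw["rs"], "chromosome": raw["chrom"],
         "cM": raw["pos"].astype(float)}
    )
    panel = GenotypePanel(gids, ["unknown"] * len(gids), dosage, mm, alleles)
    panel.n_unknown_tokens = unknown
    return panel


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno).to_csv(path, index=False)
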