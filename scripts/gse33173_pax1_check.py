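#!/usr/bin/env python
"""Recompute the Pax1 fold change between double-knockout and control IVD
samples from a locally downloaded GEO series matrix (GSE33173), using the
package's normalization and fold-change rules.

This is an optional cross-check against published expression data for the
Sox5/Sox6 knockout series; it needs a network download first and is therefore
not part of the test suite:

    1. download GSE33173_series_matrix.txt (gunzipped) from GEO
    2. python scripts/gse33173_pax1_check.py --series-matrix <path> \
           --control-gsm GSM...,GSM... --ko-gsm GSM...,GSM...

The script quantile normalizes the sample columns, collapses Pax1 probes to
the highest-mean probe, and prints the signed fold change of the knockout
group over the control group.
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd

from dosereg.differential_expression import fold_change
from dosereg.io_formats import ExpressionMatrix
from dosereg.preprocess import quantile_normalize

PAX1_PROBE_HINTS = ("Pax1", "PAX1")


def read_series_matrix(path: str) -> pd.DataFrame:
    rows = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                rows.append(line.rstrip("\n").split("\t"))
    df = pd.DataFrame(rows[1:], columns=[c.strip('"') for c in rows[0]])
    df = df.set_index(df.columns[0])
    df.index = [i.strip('"') for i in df.index]
    return df.apply(pd.to_numeric, errors="coerce")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--series-matrix", required=True)
    ap.add_argument("--control-gsm", required=True,
                    help="comma-separated control sample accessions")
    ap.add_argument("--ko-gsm", required=True,
                    help="comma-separated double-knockout sample accessions")
    ap.add_argument("--probe", default=None,
                    help="explicit Pax1 probe id (otherwise pass a platform "
                         "annotation via --annotation to map symbols)")
    ap.add_argument("--annotation", default=None,
                    help="tab-delimited platform table with ID and Symbol columns")
    args = ap.parse_args()

    table = read_series_matrix(args.series_matrix)
    control = args.control_gsm.split(",")
    ko = args.ko_gsm.split(",")
    table = table[control + ko].dropna()

    symbols = {}
    if args.annotation:
        ann = pd.read_csv(args.annotation, sep="\t", dtype=str)
        id_col = "ID" if "ID" in ann.columns else ann.columns[0]
        sym_col = "Symbol" if "Symbol" in ann.columns else ann.columns[1]
        symbols = dict(zip(ann[id_col], ann[sym_col]))

    matrix = ExpressionMatrix(
        table, pd.DataFrame(0.99, index=table.index, columns=table.columns),
        symbols or {p: p for p in table.index})
    norm = quantile_normalize(matrix)

    if args.probe:
        probes = [args.probe]
    else:
        probes = [p for p in norm.probe_ids
                  if any(h in str(symbols.get(p, p)) for h in PAX1_PROBE_HINTS)]
    if not probes:
        raise SystemExit("no Pax1 probe found; pass --probe or --annotation")
    means = norm.intensities.loc[probes].mean(axis=1)
    probe = means.idxmax()

    mean_control = float(norm.intensities.loc[probe, control].mean())
    mean_ko = float(norm.intensities.loc[probe, ko].mean())
    fc_lin, fc_signed = fold_change(mean_control, mean_ko)
    print(f"probe {probe}: control mean {mean_control:.1f}, "
          f"KO mean {mean_ko:.1f}, signed FC {fc_signed:+.2f}")


if __name__ == "__main__":
    main()
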