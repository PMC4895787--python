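"""Plain-text readers/writers for all on-disk formats.

Formats (all TSV unless noted, all carrying a ``# coalmap <kind> v1``
header comment):

* alignment — first columns ``sample``, ``population``; remaining columns
  one site each, header = site ID (``L<locus>_S<index>`` for simulated
  data); entries 0/1.  An ms-style text alternative (``segsites:`` /
  ``positions:`` blocks) is supported for interoperability.
* breakpoints — ``partition_id``, ``start_site``, ``end_site`` with
  1-based inclusive site coordinates (internally partitions are 0-based
  half-open; the conversion lives here and only here).
* phenotype — ``sample``, ``y``.
* causal truth — ``site_id``, ``site``, ``locus``, ``maf``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import HaploidAlignment
from .partition import PartitionSet

__all__ = [
    "write_alignment_tsv",
    "read_alignment_tsv",
    "write_ms",
    "read_ms",
    "write_breakpoints",
    "read_breakpoints",
    "write_phenotype",
    "read_phenotype",
    "write_causal",
    "read_causal",
    "validate_inputs",
    "ValidationError",
]

_VERSION = "v1"


class ValidationError(ValueError):
    """Cross-file consistency violation (sample sets, ranges, values)."""


def _write_df(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# coalmap {kind} {_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_df(path, kind: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- alignment ---------------------------------------------------------------


def write_alignment_tsv(aln: HaploidAlignment, path) -> None:
    pops = aln.populations or ["."] * aln.n_samples
    df = pd.DataFrame(aln.genotypes, columns=aln.site_ids)
    df.insert(0, "population", pops)
    df.insert(0, "sample", aln.sample_ids)
    _write_df(df, path, "alignment")


def read_alignment_tsv(path) -> HaploidAlignment:
    df = _read_df(path, "alignment")
    if df.columns[0] != "sample":
        raise ValidationError("alignment TSV must start with a 'sample' column")
    has_pop = len(df.columns) > 1 and df.columns[1] == "population"
    meta_cols = 2 if has_pop else 1
    samples = df["sample"].astype(str).tolist()
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs: {dup}")
    site_ids = [str(c) for c in df.columns[meta_cols:]]
    G = df.iloc[:, meta_cols:].to_numpy()
    bad = ~np.isin(G, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary value {G[i, j]!r} at sample {samples[i]!r}, "
            f"site {site_ids[j]!r}"
        )
    pops = df["population"].astype(str).tolist() if has_pop else None
    if pops is not None and all(p == "." for p in pops):
        pops = None
    return HaploidAlignment(
        genotypes=G.astype(np.int8),
        sample_ids=samples,
        populations=pops,
        site_ids=site_ids,
    )


def write_ms(aln: HaploidAlignment, path) -> None:
    """ms-style text: one block per alignment (all loci concatenated)."""
    with Path(path).open("w") as fh:
        fh.write("coalmap ms-style output\n\n//\n")
        fh.write(f"segsites: {aln.n_sites}\n")
        # global coordinates: locus index + within-locus position, scaled
        nl = int(aln.locus_index.max()) + 1 if aln.n_sites else 1
        gpos = (aln.locus_index + aln.positions) / nl
        fh.write("positions: " + " ".join(f"{p:.6f}" for p in gpos) + "\n")
        for row in aln.genotypes:
            fh.write("".join(str(int(v)) for v in row) + "\n")


def read_ms(path_or_text) -> HaploidAlignment:
    """Parse the first replicate block of ms-style output."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    lines = _io.StringIO(text).read().splitlines()
    seg = None
    positions = None
    haplotypes: list[str] = []
    for line in lines:
        line = line.strip()
        if line.startswith("segsites:"):
            seg = int(line.split(":", 1)[1])
        elif line.startswith("positions:"):
            positions = np.array(
                [float(v) for v in line.split(":", 1)[1].split()]
            )
        elif seg is not None and line and set(line) <= {"0", "1"}:
            haplotypes.append(line)
        elif haplotypes and (line.startswith("//") or not line):
            break
    if seg is None or not haplotypes:
        raise ValidationError("no ms segsites block found")
    if any(len(h) != seg for h in haplotypes):
        raise ValidationError("haplotype length does not match segsites")
    G = np.array([[int(c) for c in h] for h in haplotypes], dtype=np.int8)
    return HaploidAlignment(
        genotypes=G,
        sample_ids=[f"hap{i:03d}" for i in range(len(haplotypes))],
        site_ids=[f"S{j}" for j in range(seg)],
        positions=positions if positions is not None else None,
        locus_index=np.zeros(seg, dtype=np.int64),
    )


# -- breakpoints -------------------------------------------------------------


def write_breakpoints(parts: PartitionSet, path) -> None:
    rows = [
        {"partition_id": ell, "start_site": s + 1, "end_site": e}
        for ell, (s, e) in enumerate(parts.ranges)
    ]
    _write_df(pd.DataFrame(rows), path, "breakpoints")


def read_breakpoints(path) -> PartitionSet:
    df = _read_df(path, "breakpoints")
    need = {"partition_id", "start_site", "end_site"}
    if not need <= set(df.columns):
        raise ValidationError(f"breakpoints TSV needs columns {sorted(need)}")
    df = df.sort_values("partition_id")
    ranges = [(int(s) - 1, int(e)) for s, e in zip(df.start_site, df.end_site)]
    try:
        return PartitionSet.from_ranges(ranges)
    except ValueError as err:
        raise ValidationError(f"invalid breakpoints: {err}") from err


# -- phenotype / causal truth ------------------------------------------------


def write_phenotype(sample_ids, y, path) -> None:
    _write_df(
        pd.DataFrame({"sample": sample_ids, "y": np.asarray(y, dtype=float)}),
        path,
        "phenotype",
    )


def read_phenotype(path) -> pd.DataFrame:
    df = _read_df(path, "phenotype")
    if not {"sample", "y"} <= set(df.columns):
        raise ValidationError("phenotype TSV needs columns sample, y")
    df["sample"] = df["sample"].astype(str)
    return df[["sample", "y"]]


def write_causal(aln: HaploidAlignment, delta, path) -> None:
    delta = np.asarray(delta, dtype=int)
    maf = aln.minor_allele_freqs()
    _write_df(
        pd.DataFrame(
            {
                "site_id": [aln.site_ids[j] for j in delta],
                "site": delta + 1,
                "locus": aln.locus_index[delta],
                "maf": maf[delta],
            }
        ),
        path,
        "causal",
    )


def read_causal(path) -> pd.DataFrame:
    return _read_df(path, "causal")


# -- cross-file validation ---------------------------------------------------


def validate_inputs(
    aln: HaploidAlignment, parts: PartitionSet, phenotype: pd.DataFrame
) -> tuple[HaploidAlignment, PartitionSet, np.ndarray]:
    """Harmonize an alignment, partition set, and phenotype table.

    The phenotype is joined on sample ID (row order may differ); the
    partition set must tile exactly the alignment's sites; phenotype
    values must be finite.  Returns the phenotype as a vector aligned to
    the alignment's sample order.
    """
    if parts.n_sites != aln.n_sites:
        raise ValidationError(
            f"breakpoints cover {parts.n_sites} sites but alignment has "
            f"{aln.n_sites}"
        )
    pheno_ids = set(phenotype["sample"])
    aln_ids = set(aln.sample_ids)
    if pheno_ids != aln_ids:
        missing = sorted(aln_ids - pheno_ids)
        extra = sorted(pheno_ids - aln_ids)
        raise ValidationError(
            f"sample sets differ (missing from phenotype: {missing[:5]}, "
            f"unknown in phenotype: {extra[:5]})"
        )
    y = (
        phenotype.drop_duplicates("sample")
        .set_index("sample")["y"]
        .reindex(aln.sample_ids)
        .to_numpy(dtype=float)
    )
    if not np.isfinite(y).all():
        bad = [aln.sample_ids[i] for i in np.flatnonzero(~np.isfinite(y))[:5]]
        raise ValidationError(f"non-finite phenotype values for samples {bad}")
    return aln, parts, y
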