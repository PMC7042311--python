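"""Readers and writers for profiles, histograms, trees and configs.

Formats are deliberately plain: presence/absence TSV matrices and
multi-sample VCF for mutational profiles, two-column CSV for distance
histograms and pmfs, newick (integer branch lengths = mutation counts)
for trees, YAML/JSON for configuration. Every file written by the
command-line tools carries a comment header with the package version,
the seed and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from .distances import SampleProfile

__all__ = [
    "read_profiles",
    "read_profiles_tsv",
    "read_profiles_vcf",
    "write_profiles_tsv",
    "read_tree",
    "load_config",
    "run_header",
]


def run_header(seed, config: dict | None = None) -> str:
    """Comment header embedding version, seed and a config digest."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# mutdist {__version__} | seed={seed} | config_sha={digest}\n"


def read_profiles(path, fmt: str | None = None, **kwargs) -> list[SampleProfile]:
    """Read sample profiles, dispatching on format or file extension."""
    path = Path(path)
    if fmt is None:
        suffixes = {s.lower() for s in path.suffixes}
        fmt = "vcf" if ".vcf" in suffixes else "tsv-matrix"
    if fmt == "tsv-matrix":
        return read_profiles_tsv(path)
    if fmt == "vcf":
        return read_profiles_vcf(path, **kwargs)
    raise ValueError(f"unknown profile format {fmt!r}")


def read_profiles_tsv(path) -> list[SampleProfile]:
    """Presence/absence matrix: rows = mutation id, columns = samples."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:
        raise ValueError(f"could not parse profile matrix {path}: {exc}") from exc
    if df.empty or not len(df.columns):
        raise ValueError(f"profile matrix {path} has no samples")
    bad = df[~df.isin([0, 1]).all(axis=1)]
    if len(bad):
        raise ValueError(
            f"profile matrix {path}: non-binary entries at rows "
            f"{list(bad.index[:5])} (line {bad.index[0]})"
        )
    return [
        SampleProfile(str(col), frozenset(df.index[df[col] == 1].astype(str)))
        for col in df.columns
    ]


def write_profiles_tsv(profiles, path, header: str | None = None) -> None:
    profiles = list(profiles)
    all_muts = sorted({m for p in profiles for m in p.mutations}, key=str)
    df = pd.DataFrame(
        {p.sample_id: [1 if m in p.mutations else 0 for m in all_muts] for p in profiles},
        index=pd.Index(all_muts, name="mutation"),
    )
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t")


def read_profiles_vcf(path, rule: str = "genotype", min_vaf: float = 0.0) -> list[SampleProfile]:
    """Multi-sample VCF to profiles.

    ``rule="genotype"``: a variant is present in a sample when its
    genotype carries any non-reference allele; missing genotypes exclude
    the variant from that sample (with a warning). ``rule="vaf"``
    additionally requires the AD-derived variant allele frequency to
    reach ``min_vaf``.
    """
    import pysam

    if rule not in ("genotype", "vaf"):
        raise ValueError(f"unknown genotype rule {rule!r}")
    vcf = pysam.VariantFile(str(path))
    sample_names = list(vcf.header.samples)
    if not sample_names:
        raise ValueError(f"VCF {path} has no sample columns")
    muts: dict[str, set[str]] = {s: set() for s in sample_names}
    n_missing = 0
    for rec in vcf:
        for alt_idx, alt in enumerate(rec.alts or (), start=1):
            mut_id = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            for s in sample_names:
                data = rec.samples[s]
                gt = data.get("GT")
                if gt is None or all(a is None for a in gt):
                    n_missing += 1
                    continue
                if alt_idx not in [a for a in gt if a is not None]:
                    continue
                if rule == "vaf":
                    ad = data.get("AD")
                    if ad is None or ad[0] is None:
                        n_missing += 1
                        continue
                    depth = sum(a for a in ad if a is not None)
                    if depth == 0 or ad[alt_idx] / depth < min_vaf:
                        continue
                muts[s].add(mut_id)
    if n_missing:
        warnings.warn(
            f"{n_missing} sample genotypes missing in {path}; "
            "the affected variants were excluded from those samples",
            stacklevel=2,
        )
    return [SampleProfile(s, frozenset(muts[s])) for s in sample_names]


def read_tree(path):
    """Newick tree with branch lengths interpreted as mutation counts."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def load_config(path) -> dict:
    """YAML or JSON configuration file to a plain dict."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
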