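"""Small published reference datasets and synthetic stand-ins.

The nine candidate SNVs for equine juvenile spinocerebellar ataxia (EJSCA)
on EquCab3.0 chr11 are public study results and serve as fixture inputs for
the region and exclusion operations.  The 77-variant association table is
not redistributed here; ``synthetic_association_table`` builds a synthetic
stand-in with the same shape (77 region variants of which exactly the nine
candidates are unseen in other breeds).
"""

from __future__ import annotations

import numpy as np

from .segregation import VariantAnnotation, VariantRecord

HOME_BREED = "Quarter Horse"

# chrom, pos (1-based), ref, alt, gene, effect, impact
EJSCA_CANDIDATE_VARIANTS: list[tuple] = [
    ("11", 6963986, "C", "T", "FADS6", "synonymous_variant", "LOW"),
    ("11", 6973334, "G", "C", "FDXR", "intron_variant", "MODIFIER"),
    ("11", 6973640, "T", "C", "FDXR", "intron_variant", "MODIFIER"),
    ("11", 6976294, "C", "T", "FDXR", "intron_variant", "MODIFIER"),
    ("11", 6976720, "C", "T", "FDXR", "intron_variant", "MODIFIER"),
    ("11", 6991960, "A", "G", "GRIN2C", "intron_variant", "MODIFIER"),
    ("11", 7024027, "C", "T", "TMEM104", "intron_variant", "MODIFIER"),
    ("11", 7025248, "C", "T", "TMEM104", "intron_variant", "MODIFIER"),
    ("11", 7045999, "C", "G", "TMEM104", "intron_variant", "MODIFIER"),
]

OTHER_BREEDS = ("Arabian", "Thoroughbred", "Standardbred", "Morgan", "Icelandic")


def candidate_variant_records() -> list[VariantRecord]:
    """The nine published candidate SNVs as bare variant records."""
    out = []
    for chrom, pos, ref, alt, gene, effect, impact in EJSCA_CANDIDATE_VARIANTS:
        out.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                annotations=[VariantAnnotation(gene=gene, effect=effect, impact=impact, allele=alt)],
            )
        )
    return out


def synthetic_association_table(seed: int = 0):
    """Synthetic stand-in for the 77-variant association table.

    Returns ``(variants, observations)``: 77 variant records spanning the
    published candidate region, with cross-population observations marking
    all but the nine candidate variants as seen in at least one other
    breed (some also in the home breed).
    """
    rng = np.random.default_rng(seed)
    candidates = candidate_variant_records()
    lo = min(v.pos for v in candidates)
    hi = max(v.pos for v in candidates)
    taken = {v.pos for v in candidates}
    variants = list(candidates)
    observations: dict[tuple, set] = {}
    genes = ["FADS6", "FDXR", "GRIN2C", "TMEM104"]
    bases = "ACGT"
    while len(variants) < 77:
        pos = int(rng.integers(lo + 1, hi))
        if pos in taken:
            continue
        taken.add(pos)
        ref, alt = (str(b) for b in rng.choice(list(bases), size=2, replace=False))
        v = VariantRecord(
            chrom="11", pos=pos, ref=ref, alt=alt,
            annotations=[
                VariantAnnotation(
                    gene=str(rng.choice(genes)), effect="intron_variant",
                    impact="MODIFIER", allele=alt,
                )
            ],
        )
        variants.append(v)
        breeds = set(rng.choice(OTHER_BREEDS, size=int(rng.integers(1, 3)), replace=False))
        if rng.random() < 0.3:
            breeds.add(HOME_BREED)
        observations[v.key] = breeds
    # some candidates are recorded as seen in the home breed only
    for v in candidates[:3]:
        observations[v.key] = {HOME_BREED}
    variants.sort(key=lambda v: v.pos)
    return variants, observations
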