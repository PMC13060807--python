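"""DEG sets and the DF1 directional signature-matching score.

DF1 ("Differential F1") compares two perturbation signatures at a DEG
threshold T.  Genes exceeding |z| > T form each signature's DEG set; shared
DEGs agreeing in direction (STP) and conflicting (OTP), plus the private
DEGs of either side (FP, FN), feed smoothed precision/recall/F1 components
whose supportive-minus-opposing combination yields a signed score in
(-1, 1).  A positive DF1 means the two perturbations moved the
transcriptome the same way; under the signature-reversion paradigm that is
read as a supportive gene-gene relation but an *inhibitory* drug-gene one
(a drug mimicking a gene's disruption likely opposes that gene).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .containers import DEGSet, MatchComponents, PerturbationSignature

__all__ = ["deg_set", "match_counts", "df1_score", "df1_match", "interpret_direction"]


def deg_set(sig: PerturbationSignature, threshold: float) -> DEGSet:
    """Signed DEGs of a signature: genes with |consensus z| strictly > T."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1)")
    z = sig.consensus_z
    mask = z.abs() > threshold
    signs = {g: (1 if v > 0 else -1) for g, v in z[mask].items()}
    return DEGSet(sig.perturbagen_id, threshold, signs)


def match_counts(
    deg_a: DEGSet, deg_b: DEGSet, universe: Iterable[str]
) -> tuple[int, int, int, int]:
    """Classify every gene of the shared measured universe for a pair.

    Only genes measured by both signatures are considered, so that platform
    coverage differences do not inflate the private-DEG counts.  Returns
    (STP, OTP, FP, FN): same-sign shared DEGs, opposite-sign shared DEGs,
    DEGs private to A, DEGs private to B.
    """
    uni = set(universe)
    a = {g: s for g, s in deg_a.signs.items() if g in uni}
    b = {g: s for g, s in deg_b.signs.items() if g in uni}
    stp = otp = 0
    for g, s in a.items():
        if g in b:
            if s == b[g]:
                stp += 1
            else:
                otp += 1
    fp = len(a) - stp - otp
    fn = len(b) - stp - otp
    return stp, otp, fp, fn


def df1_score(
    stp: int, otp: int, fp: int, fn: int, threshold: float = 0.0
) -> MatchComponents:
    """Smoothed directional-F1 components from the four match counts.

    SP = STP/(STP+FP+OTP+1)        OP = OTP/(OTP+FP+STP+1)
    SR = STP/(STP+FN+1)            OR = OTP/(OTP+FN+1)
    SF1 = 3*SP*SR/(SP+SR+1)        OF1 = 3*OP*OR/(OP+OR+1)
    DF1 = 2*(SF1-OF1)*|SF1-OF1| / (SF1+OF1+1)

    The +1 denominators penalize sparse signatures; the quadratic
    supportive-minus-opposing form penalizes conflicting evidence in both
    directions.  All-zero counts are legal and give DF1 = 0.
    """
    if min(stp, otp, fp, fn) < 0:
        raise ValueError("match counts must be nonnegative")
    sp = stp / (stp + fp + otp + 1)
    op = otp / (otp + fp + stp + 1)
    sr = stp / (stp + fn + 1)
    orr = otp / (otp + fn + 1)
    sf1 = 3 * sp * sr / (sp + sr + 1)
    of1 = 3 * op * orr / (op + orr + 1)
    df1 = 2 * (sf1 - of1) * abs(sf1 - of1) / (sf1 + of1 + 1)
    return MatchComponents(
        STP=stp, OTP=otp, FP=fp, FN=fn,
        SP=sp, OP=op, SR=sr, OR=orr,
        SF1=sf1, OF1=of1, DF1=df1,
        threshold=threshold,
    )


def df1_match(
    sig_a: PerturbationSignature,
    sig_b: PerturbationSignature,
    threshold: float,
) -> MatchComponents:
    """DF1 between two signatures at one threshold (shared-universe rule)."""
    universe = sig_a.genes.intersection(sig_b.genes)
    a = deg_set(sig_a, threshold)
    b = deg_set(sig_b, threshold)
    stp, otp, fp, fn = match_counts(a, b, universe)
    return df1_score(stp, otp, fp, fn, threshold)


def interpret_direction(df1: float, relation_class: str) -> Optional[int]:
    """Map a signed DF1 to a predicted relation direction.

    gene_gene: similar disruption signatures (DF1 > 0) imply the genes
    support each other (+1); opposing signatures imply inhibition (-1).
    drug_gene: a drug mimicking a gene's disruption (DF1 > 0) likely
    inhibits that gene (-1), and one opposing the disruption supports it
    (+1).  DF1 == 0 carries no direction (None).
    """
    if relation_class not in ("gene_gene", "drug_gene"):
        raise ValueError(f"unknown relation class {relation_class!r}")
    if df1 == 0:
        return None
    sign = 1 if df1 > 0 else -1
    return sign if relation_class == "gene_gene" else -sign
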