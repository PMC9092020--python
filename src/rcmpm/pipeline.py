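"""Glue between feature extraction, graph construction, and the model.

When only a single rough contact map is available (the synthetic generator
produces one), it fills both rough-map channels of the pairwise tensor,
which correspond to the two upstream score sources of the full feature set.
"""

from __future__ import annotations

from pathlib import Path

from rcmpm.contact_geometry import ContactMap
from rcmpm.graph_builder import build_contact_graph
from rcmpm.io_formats import MSA, PSSMProfile, ScoreMatrix, parse_msa, parse_score_matrix
from rcmpm.model import ModelConfig, TrainExample
from rcmpm.pair_features import (
    PairFeatureTensor,
    PotentialTable,
    apc_matrix,
    assemble_pair_tensor,
    mi_matrix,
    potential_matrix,
)
from rcmpm.seq_features import (
    SeqFeatureTensor,
    StructureProfile,
    assemble_seq_tensor,
    parse_profile,
    pssm_from_msa,
)
from rcmpm.synthetic_data import SyntheticProtein


def build_feature_tensors(
    msa: MSA,
    rough_a: ScoreMatrix,
    profile: StructureProfile,
    rough_b: ScoreMatrix | None = None,
    pssm: PSSMProfile | None = None,
    potential: PotentialTable | None = None,
) -> tuple[SeqFeatureTensor, PairFeatureTensor]:
    """Assemble X_seq (L x 26) and X_pair (L x L x 5) for one protein."""
    if pssm is None:
        pssm = pssm_from_msa(msa)
    if rough_b is None:
        rough_b = rough_a
    x_seq = assemble_seq_tensor(pssm, profile)
    mi = mi_matrix(msa)
    x_pair = assemble_pair_tensor(
        rough_a, rough_b, mi, apc_matrix(mi), potential_matrix(msa, potential)
    )
    return x_seq, x_pair


def featurize_protein(
    protein: SyntheticProtein, config: ModelConfig
) -> TrainExample:
    """Turn one synthetic fixture into a training example."""
    x_seq, x_pair = build_feature_tensors(
        protein.msa, protein.rough, protein.profile
    )
    graph = build_contact_graph(
        protein.rough, config.edge_threshold, config.weighted_graph
    )
    return TrainExample(
        x_seq=x_seq.features, x_pair=x_pair.channels,
        graph=graph, truth=protein.truth,
    )


def featurize_directory(protein_dir: str | Path, config: ModelConfig) -> TrainExample:
    """Build a training example from an on-disk protein directory
    (msa.fasta, rough.mat, profile.tsv, truth.mat)."""
    protein_dir = Path(protein_dir)
    msa = parse_msa(protein_dir / "msa.fasta")
    rough = parse_score_matrix(protein_dir / "rough.mat", dialect="dense")
    profile = parse_profile(protein_dir / "profile.tsv")
    x_seq, x_pair = build_feature_tensors(msa, rough, profile)
    graph = build_contact_graph(rough, config.edge_threshold, config.weighted_graph)
    truth_path = protein_dir / "truth.mat"
    truth = None
    if truth_path.exists():
        truth = ContactMap(parse_score_matrix(truth_path, dialect="dense").values)
    return TrainExample(
        x_seq=x_seq.features, x_pair=x_pair.channels, graph=graph, truth=truth
    )
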