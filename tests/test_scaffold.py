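"""Building-block generation and scaffold assembly chemistry."""

import pytest
from rdkit import Chem

from scaffoldmine.modules import classify_all, segment_into_modules
from scaffoldmine.scaffold import (
    BuildingBlock,
    SubstrateChemistryTable,
    apply_previous_block_rule,
    assemble,
    assemble_chain,
    blocks_from_modules,
    module_to_building_block,
)


def _classified(arrangement, substrate=None):
    (m,) = classify_all(segment_into_modules(arrangement.split("-")))
    m.substrate = substrate
    return m


def _chain(specs):
    """Build blocks from (arrangement, substrate) pairs, in order."""
    modules = [_classified(a, s) for a, s in specs]
    return blocks_from_modules(modules)


def canon(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


def strip_stereo(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


class TestBuildingBlocks:
    def test_glycine_loading_block_has_no_stereo(self):
        blk = module_to_building_block(_classified("A-PCP", "G"))
        assert blk.kind == "NRP" and blk.loading and blk.alpha_stereo == "unset"

    def test_methylmalonyl_with_cmt_doubles_alpha_methyls(self):
        m = _classified("KS-AT-cMT-ACP", "methylmalonyl")
        blk = module_to_building_block(m)
        assert blk.alpha_methyls == 2

    def test_double_methylation_caps_reduction_at_ketone(self):
        m = _classified("KS-AT-DH-cMT-KR-ACP", "methylmalonyl")
        blk = module_to_building_block(m)
        assert blk.alpha_methyls == 2
        assert blk.beta_state == "ketone"  # enoyl impossible at a gem-dimethyl α

    def test_omt_after_kr_gives_methoxy_beta(self):
        blk = module_to_building_block(_classified("KS-AT-oMT-KR-ACP", "malonyl"))
        assert blk.beta_state == "methoxy"

    def test_trans_at_module_without_substrate_gets_malonyl_like_block(self):
        blk = module_to_building_block(_classified("KS-tAT_d-KR-ACP"))
        assert blk.kind == "PK" and blk.side_chain == ""

    def test_non_functional_module_is_rejected(self):
        with pytest.raises(ValueError):
            module_to_building_block(_classified("C-PCP"))

    def test_unregistered_substrate_is_an_error(self):
        with pytest.raises(KeyError, match="unobtainium"):
            module_to_building_block(_classified("C-A-PCP", "unobtainium"))

    def test_invariant_loading_pk_without_beta(self):
        with pytest.raises(ValueError):
            BuildingBlock(kind="PK", loading=True, beta_state="ketone")

    def test_invariant_double_methyl_restricts_beta(self):
        with pytest.raises(ValueError):
            BuildingBlock(kind="PK", alpha_methyls=2, beta_state="enoyl")


class TestPreviousBlockRule:
    def test_three_module_chain_beta_states(self):
        modules = [
            _classified("A-PCP", "G"),
            _classified("KS-AT-DH-KR-PCP", "malonyl"),      # enoyl
            _classified("KS-AT-DH-ER-KR-ACP-TE", "malonyl"),  # alkyl
        ]
        usable = [m for m in modules]
        blocks = [module_to_building_block(m) for m in usable]
        shifted = apply_previous_block_rule(blocks, usable)
        pk_states = [b.beta_state for b in shifted if b.kind == "PK"]
        assert pk_states == ["enoyl", "alkyl"]
        assert shifted[-1].terminal_cap == "carboxyl"

    def test_single_loading_module_is_unchanged(self):
        m = _classified("A-PCP", "G")
        blocks = [module_to_building_block(m)]
        assert apply_previous_block_rule(blocks, [m]) == blocks


class TestAssembly:
    def test_gly_ala_dipeptide_matches_hand_drawn_structure(self):
        chain = _chain([("A-PCP", "G"), ("C-A-PCP-TE", "A")])
        smiles = assemble_chain(chain)
        assert strip_stereo(smiles) == strip_stereo(canon("NCC(=O)NC(C)C(=O)O"))
        # the alanine α-carbon carries the L (S) configuration
        assert smiles == canon("NCC(=O)N[C@@H](C)C(=O)O")

    def test_single_loading_module_with_te_gives_the_free_acid(self):
        chain = _chain([("A-PCP-TE", "G")])
        assert assemble_chain(chain) == canon("NCC(=O)O")

    def test_epimerization_yields_d_configuration(self):
        l_chain = _chain([("A-PCP", "G"), ("C-A-PCP-TE", "A")])
        d_chain = _chain([("A-PCP", "G"), ("C-A-PCP-E", "A")])
        d_chain[-1] = type(d_chain[-1])(**{**d_chain[-1].__dict__, "terminal_cap": "carboxyl"})
        l_smiles = assemble_chain(l_chain)
        d_smiles = assemble_chain(d_chain)
        assert d_smiles == canon("NCC(=O)N[C@H](C)C(=O)O")
        assert strip_stereo(l_smiles) == strip_stereo(d_smiles)
        assert l_smiles != d_smiles

    def test_pk_hydroxyl_chain_gives_three_hydroxybutyrate(self):
        chain = _chain([("KSQ-AT-ACP", "malonyl"), ("KS-AT-KR-ACP-TE", "malonyl")])
        assert assemble_chain(chain) == canon("CC(O)CC(=O)O")

    def test_pk_enoyl_alkyl_chain(self):
        chain = _chain(
            [
                ("KSQ-AT-ACP", "malonyl"),
                ("KS-AT-DH-KR-ACP", "malonyl"),
                ("KS-AT-DH-ER-KR-ACP-TE", "malonyl"),
            ]
        )
        assert assemble_chain(chain) == canon("CC=CCCC(=O)O")

    def test_td_release_gives_terminal_alcohol(self):
        chain = _chain([("A-PCP-TD", "G")])
        assert assemble_chain(chain) == canon("NCCO")

    def test_n_methylation_adds_exactly_one_carbon(self):
        plain = _chain([("A-PCP", "G"), ("C-A-PCP-TE", "A")])
        methylated = _chain([("A-PCP", "G"), ("C-A-nMT-PCP-TE", "A")])
        n_plain = Chem.MolFromSmiles(assemble_chain(plain)).GetNumAtoms()
        n_meth = Chem.MolFromSmiles(assemble_chain(methylated)).GetNumAtoms()
        assert n_meth == n_plain + 1

    def test_mixed_chain_pk_after_nrp_bonds_at_beta_carbonyl(self):
        chain = _chain([("A-PCP", "G"), ("KS-AT-ACP-TE", "malonyl")])
        # glycine then a ketide extension: N-CH2-C(=O)-CH2-COOH
        assert assemble_chain(chain) == canon("NCC(=O)CC(=O)O")

    def test_disconnected_chains_become_separate_fragments(self):
        c1 = _chain([("A-PCP", "G")])
        c2 = _chain([("A-PCP", "A")])
        scaffold = assemble([c1, c2])
        assert len(scaffold.fragments) == 2
        assert "." in scaffold.smiles

    def test_assembly_is_deterministic_and_canonical(self):
        chain = _chain([("A-PCP", "V"), ("C-A-PCP-TE", "F")])
        s1 = assemble_chain(chain)
        s2 = assemble_chain(_chain([("A-PCP", "V"), ("C-A-PCP-TE", "F")]))
        assert s1 == s2 == canon(s1)  # idempotent re-canonicalization

    def test_proline_template_block(self):
        chain = _chain([("A-PCP", "G"), ("C-A-PCP-TE", "P")])
        mol = Chem.MolFromSmiles(assemble_chain(chain))
        assert mol is not None
        assert mol.GetRingInfo().NumRings() == 1

    def test_empty_chain_is_an_error(self):
        with pytest.raises(ValueError):
            assemble_chain([])


class TestHeavyAtomAccounting:
    def test_fragment_atom_count_matches_block_templates(self):
        # NRP residue contributes N + Cα + side chain; each junction adds one
        # carbonyl carbon + oxygen; the TE cap adds COOH (1 C + 2 O)
        chain = _chain([("A-PCP", "A"), ("C-A-PCP", "V"), ("C-A-PCP-TE", "G")])
        mol = Chem.MolFromSmiles(assemble_chain(chain))
        side_chain_atoms = {"A": 1, "V": 3, "G": 0}
        expected = (
            sum(2 + side_chain_atoms[s] for s in ("A", "V", "G"))  # N + Cα + R
            + 2 * 2  # two amide junctions: C + O
            + 3      # terminal carboxyl: C + 2 O
        )
        assert mol.GetNumAtoms() == expected


class TestChemistryTable:
    def test_default_table_covers_all_classifier_labels(self):
        table = SubstrateChemistryTable.default()
        for label in ["malonyl", "methylmalonyl", "ethylmalonyl", "methoxymalonyl"]:
            assert label in table
        for label in "ACDEFGHIKLNPQRSTVWY":
            assert label in table
        for label in ["aad", "bht", "dab", "dhb", "dhbu", "dhpg", "horn", "hpg",
                      "orn", "pip"]:
            assert label in table

    def test_every_entry_parses_to_a_molecule(self):
        # construction validates fragments; loading the default must not raise
        SubstrateChemistryTable.default()
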