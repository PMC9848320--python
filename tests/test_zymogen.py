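"""Catalytic-domain delimitation, latency switch and curation verdicts."""

import numpy as np
import pytest

from astascan.motifs import find_zinc_site
from astascan.simulate import (
    DECOY_CLASSES,
    GeneratorConfig,
    make_canonical_cd,
    make_decoys,
    make_precursor,
)
from astascan.zymogen import (
    REASON_CODES,
    NoProdomainError,
    ValidatorConfig,
    annotate_cd,
    annotate_zymogen,
    classify_hatching_cys,
    validate_astacin,
)


def _cd_only(rng):
    cd, anchors = make_canonical_cd(GeneratorConfig(), rng)
    return cd, anchors


class TestAnnotateCD:
    def test_spans_close_on_generated_geometry(self, gen_cfg, rng, validator_cfg):
        rec, truth = make_precursor("basic", gen_cfg, rng)
        site = find_zinc_site(rec.sequence)
        cd = annotate_cd(rec.sequence, site, validator_cfg)
        assert (cd.cd_start, cd.cd_end) == truth.cd_span
        assert not cd.truncated

    def test_archetype_disulfide_census(self, rng):
        # four CD cysteines (three N-subdomain + one C-subdomain) -> 2 bridges
        seq, _ = _cd_only(rng)
        cd = annotate_cd(seq, find_zinc_site(seq))
        assert len(cd.cys_positions) == 4
        assert cd.n_potential_disulfides == 2
        assert cd.n_subdomain_cys_extra == 0

    def test_truncation_flag(self, rng):
        seq, anchors = _cd_only(rng)
        clipped = seq[anchors["his1"] - 50 :]  # only 50 residues before His1
        cd = annotate_cd(clipped, find_zinc_site(clipped))
        assert cd.truncated
        assert cd.cd_start == 0

    def test_cd_length_equals_span(self, rng):
        seq, _ = _cd_only(rng)
        cd = annotate_cd(seq, find_zinc_site(seq))
        assert cd.cd_length == cd.cd_end - cd.cd_start == len(seq)


class TestAnnotateZymogen:
    def _with_pro(self, pro, rng):
        cd_seq, _ = _cd_only(rng)
        seq = pro + cd_seq
        cd = annotate_cd(seq, find_zinc_site(seq))
        return seq, cd

    def test_aspartate_switch(self, rng):
        pro = "A" * 40 + "FSGDI" + "A" * 10
        seq, cd = self._with_pro(pro, rng)
        z = annotate_zymogen(seq, cd)
        assert (z.pro_start, z.pro_end) == (0, 55)
        assert z.switch_type == "aspartate"
        assert z.switch_pos == 43  # the Asp of FSGDI
        assert z.activation_site == 55

    def test_cysteine_switch_when_motif_absent(self, rng):
        pro = "A" * 5 + "C" + "A" * 34 + "FSGNI" + "A" * 10  # D->N kills the motif
        seq, cd = self._with_pro(pro, rng)
        z = annotate_zymogen(seq, cd)
        assert z.switch_type == "cysteine"
        assert z.switch_pos == 5
        assert z.fxgdi_hit is None

    def test_no_switch(self, rng):
        seq, cd = self._with_pro("A" * 55, rng)
        z = annotate_zymogen(seq, cd)
        assert z.switch_type == "none"
        assert z.switch_pos is None

    def test_nearest_motif_wins(self, rng):
        pro = "FSGDI" + "A" * 30 + "FTGDI" + "A" * 15
        seq, cd = self._with_pro(pro, rng)
        z = annotate_zymogen(seq, cd)
        assert z.fxgdi_hit.start == 35  # downstream instance, nearest activation

    def test_mature_only_raises(self, rng):
        seq, _ = _cd_only(rng)
        cd = annotate_cd(seq, find_zinc_site(seq))
        with pytest.raises(NoProdomainError):
            annotate_zymogen(seq, cd)


class TestValidateAstacin:
    def test_generated_positive_accepted(self, basic_precursor, validator_cfg):
        rec, truth = basic_precursor
        report = validate_astacin(rec, validator_cfg)
        assert report.accepted
        assert report.reason_codes == ()
        assert not report.xenologue_flag
        assert (report.cd.cd_start, report.cd.cd_end) == truth.cd_span
        assert (report.zymogen.pro_start, report.zymogen.pro_end) == truth.pro_span
        assert report.zymogen.switch_pos == truth.anchors["switch_asp"]

    def test_determinism(self, basic_precursor, validator_cfg):
        rec, _ = basic_precursor
        assert validate_astacin(rec, validator_cfg) == validate_astacin(rec, validator_cfg)

    def test_every_decoy_gets_its_intended_reason(self, gen_cfg):
        rng = np.random.default_rng(5)
        cfg = ValidatorConfig(signal_end=gen_cfg.signal_length)
        decoys = make_decoys(len(DECOY_CLASSES) * 3, gen_cfg, rng)
        assert len(decoys) == 27
        for rec, truth in decoys:
            report = validate_astacin(rec, cfg)
            assert not report.accepted
            assert report.reason_codes == (truth.intended_reason,), rec.id

    def test_cysteine_switch_flags_xenologue(self, gen_cfg):
        rng = np.random.default_rng(6)
        cfg = ValidatorConfig(signal_end=gen_cfg.signal_length)
        sub = GeneratorConfig(decoy_fractions={"cys_switch": 1.0})
        (rec, _), = make_decoys(1, sub, rng)
        report = validate_astacin(rec, cfg)
        assert report.reason_codes == ("no_latency_switch",)
        assert report.zymogen.switch_type == "cysteine"
        assert report.xenologue_flag

    def test_non_holozoan_clade_flags_xenologue(self, basic_precursor, validator_cfg):
        rec, _ = basic_precursor
        report = validate_astacin(rec.with_metadata(clade="Bacteria"), validator_cfg)
        assert report.accepted  # sequence criteria still pass
        assert report.xenologue_flag

    def test_short_prodomain_rejected(self, gen_cfg):
        rng = np.random.default_rng(8)
        sub = GeneratorConfig(pro_length_bounds=(33, 33))
        rec, _ = make_precursor("basic", sub, rng)
        report = validate_astacin(rec, ValidatorConfig(signal_end=sub.signal_length))
        assert report.reason_codes == ("pro_too_short",)

    def test_reason_codes_stay_in_vocabulary(self, gen_cfg):
        rng = np.random.default_rng(9)
        cfg = ValidatorConfig(signal_end=gen_cfg.signal_length)
        for rec, _ in make_decoys(len(DECOY_CLASSES), gen_cfg, rng):
            for code in validate_astacin(rec, cfg).reason_codes:
                assert code in REASON_CODES

    def test_narrowing_cd_window_is_monotone(self, basic_precursor, validator_cfg):
        # a stricter config can only lose acceptances, never gain them
        rec, _ = basic_precursor
        wide = validate_astacin(rec, validator_cfg)
        narrow_cfg = ValidatorConfig(
            signal_end=validator_cfg.signal_end, cd_length_window=(170, 180)
        )
        narrow = validate_astacin(rec, narrow_cfg)
        assert wide.accepted and not narrow.accepted
        assert narrow.reason_codes == ("cd_length_out_of_window",)


class TestHatchingCys:
    def test_basic_has_no_extra_pair(self, gen_cfg, rng, validator_cfg):
        rec, _ = make_precursor("basic", gen_cfg, rng)
        report = validate_astacin(rec, validator_cfg)
        assert not classify_hatching_cys(report.cd, validator_cfg)

    def test_hatching_has_extra_pair(self, gen_cfg, rng, validator_cfg):
        rec, _ = make_precursor("hatching_like", gen_cfg, rng)
        report = validate_astacin(rec, validator_cfg)
        assert report.cd.n_subdomain_cys_extra == 2
        assert classify_hatching_cys(report.cd, validator_cfg)

    def test_single_extra_cys_is_not_a_pair(self, gen_cfg, rng, validator_cfg):
        rec, truth = make_precursor("basic", gen_cfg, rng)
        s = list(rec.sequence)
        pos = truth.cd_span[0] + 10  # N-subdomain background position
        assert s[pos] != "C"
        s[pos] = "C"
        report = validate_astacin(rec.with_metadata(), validator_cfg)
        mutated = validate_astacin(
            type(rec)(rec.id, "".join(s)), validator_cfg
        )
        assert mutated.cd.n_subdomain_cys_extra == 1
        assert not classify_hatching_cys(mutated.cd, validator_cfg)
        assert report.cd.n_subdomain_cys_extra == 0
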