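import json

import pytest
import yaml
from click.testing import CliRunner

from inclufit import gallery
from inclufit.cli import main as cli_main
from inclufit.consanguinity import IslandModelSpec, island_model_ibd
from inclufit.core import SpecificationError, inclusive_fitness_effect
from inclufit.interface import (
    generate_fixture,
    model_from_dict,
    model_to_dict,
    parse_model_spec,
    reference_effect,
    serialize_model,
    write_fixture,
)

MINIMAL_HELPING = """
schema: 1
classes:
  - {label: X, u: 1, c: 1.0}
actor: {class: X}
pools:
  - {label: k, class: X, R: 0.0, note: population at large}
  - {label: m, class: X, R: 0.0}
consanguinity:
  R_ii: 0.5
  R:
    j: 0.125
deviations:
  - {participant: actor, class: X, delta: -0.01, pool: k}
  - {participant: j, class: X, delta: 0.06, pool: m}
"""


class TestParseModelSpec:
    def test_minimal_helping_round_trip(self, tmp_path):
        path = tmp_path / "helping.yaml"
        path.write_text(MINIMAL_HELPING)
        model = parse_model_spec(path)
        result = inclusive_fitness_effect(model)
        assert result.effect == pytest.approx(-0.01 + 0.25 * 0.06, abs=1e-15)

    def test_island_directive_matches_module(self, tmp_path):
        doc = yaml.safe_load(MINIMAL_HELPING)
        doc["consanguinity"] = {
            "R_ii": 1.0,
            "R": {"j": {"island": "patch-mate"}},
            "island": {"n": 10, "m": 0.1},
        }
        model = model_from_dict(doc)
        F = island_model_ibd(IslandModelSpec(n=10, m=0.1))
        assert model.consanguinity.R_to["j"] == F

    def test_ploidy_and_pedigree_directives(self):
        doc = yaml.safe_load(MINIMAL_HELPING)
        doc["consanguinity"] = {
            "R_ii": {"ploidy": "diploid", "f": 0.0},
            "R": {"j": {"pedigree": "full-sib"}},
        }
        model = model_from_dict(doc)
        assert model.consanguinity.R_ii == 0.5
        assert model.consanguinity.R_to["j"] == 0.25

    def test_demography_block_builds_structure(self):
        doc = yaml.safe_load(MINIMAL_HELPING)
        del doc["classes"]
        doc["demography"] = {"labels": ["X", "Y"], "matrix": [[0.4, 1.1], [1.1, 0.4]]}
        doc["pools"].append({"label": "m2", "class": "Y", "R": 0.0})
        doc["deviations"][1] = {"participant": "j", "class": "Y", "delta": 0.06, "pool": "m2"}
        model = model_from_dict(doc)
        assert model.structure.classes == ("X", "Y")
        assert model.structure.c["X"] == pytest.approx(0.5, abs=1e-10)

    def test_rejections_are_specific(self):
        doc = yaml.safe_load(MINIMAL_HELPING)
        doc["pools"][1]["class"] = "Y"  # compensator class != deviation class
        doc["classes"].append({"label": "Y", "u": 1, "c": 0.0})
        doc["classes"][0]["c"] = 1.0
        with pytest.raises(SpecificationError, match="within each class"):
            model_from_dict(doc)

        doc = yaml.safe_load(MINIMAL_HELPING)
        doc["schema"] = 99
        with pytest.raises(SpecificationError, match="schema"):
            model_from_dict(doc)

        doc = yaml.safe_load(MINIMAL_HELPING)
        del doc["deviations"][0]["pool"]
        with pytest.raises(SpecificationError, match="pool"):
            model_from_dict(doc)

        doc = yaml.safe_load(MINIMAL_HELPING)
        doc["deviations"][1]["pool"] = "nowhere"
        with pytest.raises(SpecificationError, match="nowhere"):
            model_from_dict(doc)


class TestSerializationRoundTrip:
    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_fixture_round_trip_preserves_effect(self, seed, tmp_path):
        doc, _ = generate_fixture(seed)
        model = model_from_dict(doc)
        path = tmp_path / "model.yaml"
        serialize_model(model, path)
        again = parse_model_spec(path)
        assert inclusive_fitness_effect(again).effect == inclusive_fitness_effect(model).effect

    def test_gallery_model_round_trip(self, tmp_path):
        model = gallery.sex_ratio_lmc(3).if_family(0.4)
        doc = model_to_dict(model)
        again = model_from_dict(doc)
        assert inclusive_fitness_effect(again).effect == pytest.approx(
            inclusive_fitness_effect(model).effect, abs=1e-15
        )


class TestFixtures:
    def test_same_seed_same_documents(self):
        assert generate_fixture(123) == generate_fixture(123)

    @pytest.mark.parametrize("seed", range(0, 300, 7))
    def test_core_effect_matches_sidecar(self, seed):
        doc, sidecar = generate_fixture(seed)
        model = model_from_dict(doc)
        assert inclusive_fitness_effect(model).effect == pytest.approx(
            sidecar["effect"], rel=1e-12, abs=1e-12
        )

    def test_zeroed_deltas_give_zero_effect(self):
        doc, _ = generate_fixture(5)
        for dev in doc["deviations"]:
            dev["delta"] = 0.0
        model = model_from_dict(doc)
        assert reference_effect(model) == 0.0
        assert inclusive_fitness_effect(model).effect == 0.0

    def test_write_fixture_files(self, tmp_path):
        spec_path, sidecar_path = write_fixture(9, tmp_path)
        model = parse_model_spec(spec_path)
        expected = json.loads(sidecar_path.read_text())["effect"]
        assert inclusive_fitness_effect(model).effect == pytest.approx(expected, rel=1e-12)


class TestCli:
    def test_effect_command(self, tmp_path):
        path = tmp_path / "helping.yaml"
        path.write_text(MINIMAL_HELPING)
        result = CliRunner().invoke(cli_main, ["effect", str(path), "--out", str(tmp_path / "rep")])
        assert result.exit_code == 0, result.output
        assert "favoured" in result.output
        assert (tmp_path / "rep" / "helping.json").exists()

    def test_effect_command_bad_spec_fails(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("schema: 1\nclasses: []\n")
        result = CliRunner().invoke(cli_main, ["effect", str(path)])
        assert result.exit_code != 0

    def test_gallery_and_ess_commands(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["gallery", "sex_ratio_lmc", "-p", "n_foundresses=2", "--trait", "0.3"]
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, ["ess", "sex_ratio_lmc", "-p", "n_foundresses=2"])
        assert result.exit_code == 0, result.output
        root = float(result.output.splitlines()[0].split(":")[1])
        assert root == pytest.approx(0.25, abs=1e-6)

    def test_check_command_pass_and_fail_codes(self, tmp_path):
        runner = CliRunner()
        ok = runner.invoke(cli_main, [
            "check", "viscous_help",
            "-p", "B=5", "-p", "C=1", "-p", "n=4", "-p", "m=0.2", "-p", "elastic=true",
            "--out", str(tmp_path / "check.json"),
        ])
        assert ok.exit_code == 0, ok.output
        assert json.loads((tmp_path / "check.json").read_text())["passed"]
        bad = runner.invoke(cli_main, ["check", "no_such_model"])
        assert bad.exit_code != 0

    def test_fixture_command(self, tmp_path):
        result = CliRunner().invoke(
            cli_main, ["fixture", "--seed", "4", "--out", str(tmp_path / "fx")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "fixture_4.yaml").exists()
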