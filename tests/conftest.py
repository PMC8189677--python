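import subprocess
from pathlib import Path

import pytest

from provfs import Mount, TracedRunner
from provfs.config import CacheConfig, Config
from provfs.synthetic import (
    gen_pipeline,
    gen_vdf_fixtures,
    materialize_pipeline,
    materialize_tree,
)


@pytest.fixture
def vdf_mount(tmp_path):
    """A mount over the synthetic VDF fixture tree (small cache blocks)."""
    tree, config = gen_vdf_fixtures(seed=0)
    root = tmp_path / "root"
    root.mkdir()
    materialize_tree(tree, root)
    cfg = Config(
        vdf_rules=config.vdf_rules,
        cache=CacheConfig(block_size=4096, memory_limit=64 * 1024),
    )
    mount = Mount(root, cfg, disk_tier=tmp_path / "cache")
    yield mount, tree, root
    mount.store.close()


@pytest.fixture
def recorded_pipeline(tmp_path):
    """A 4-stage pipeline recorded under a mount; returns rich context."""
    pipeline = gen_pipeline(4, branching=2, seed=11)
    data, bindir = tmp_path / "data", tmp_path / "bin"
    data.mkdir()
    materialize_pipeline(pipeline, data, bindir)
    mount = Mount(data)
    run = TracedRunner(mount).run_pipeline(pipeline, bindir)
    yield {
        "pipeline": pipeline,
        "mount": mount,
        "store": mount.store,
        "run": run,
        "data": data,
        "bindir": bindir,
        "tmp": tmp_path,
    }
    mount.store.close()


def run_shell(cmd: str, **kw) -> bytes:
    return subprocess.run(
        ["/bin/sh", "-c", cmd], capture_output=True, check=False, **kw
    ).stdout


def direct_vdf_output(spec, source: Path, scratch: Path) -> bytes:
    """Run a VDF rule's command directly (the identity oracle)."""
    if spec.output_channel == "stdout":
        return run_shell(spec.command_for(str(source)))
    out = scratch / "direct.out"
    subprocess.run(
        ["/bin/sh", "-c", spec.command_for(str(source), str(out))], check=False
    )
    return out.read_bytes() if out.exists() else b""
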