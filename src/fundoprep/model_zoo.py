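"""Analytical layer catalog for the eleven ImageNet backbones.

Each builder enumerates every trainable layer of the backbone as
``(name, parameter_count)`` pairs, exactly as the reference ImageNet
implementations define them (convolution = Cin/groups * Cout * kH * kW
[+ Cout bias], batch-norm = 2 * C affine terms, dense = Din * Dout + Dout).
The final 1000-way ImageNet classifier is replaced by an ``n_classes``-way
dense head; everything else, including Inception-v3's auxiliary 1000-way
branch, is kept as published.

The catalog exists for exact parameter accounting of transfer-learning
heads: swapping only the last dense layer changes the total by
``d * (n_new - 1000) + (n_new - 1000)`` where ``d`` is the penultimate
width, so counts are verifiable against the published 1000-class totals.
"""

from __future__ import annotations

import math
from typing import Callable

__all__ = [
    "ARCH_NAMES",
    "IMAGENET_PARAM_COUNTS",
    "PENULTIMATE_WIDTH",
    "backbone_layers",
    "head_swap_count",
]

# Published trainable-parameter totals of the 1000-class reference models
# (torchvision definitions). Used only as an independent cross-check of the
# structural enumeration below, never as the reported count.
IMAGENET_PARAM_COUNTS: dict[str, int] = {
    "SqueezeNet": 1_235_496,
    "MobileNetv2": 3_504_872,
    "Inceptionv1": 6_624_904,
    "DenseNet121": 7_978_856,
    "EfficientNet-B3": 12_233_232,
    "ResNeXt50": 25_028_904,
    "ResNet50": 25_557_032,
    "Inceptionv3": 27_161_264,
    "EfficientNet-B7": 66_347_960,
    "WideResNet50": 68_883_240,
    "VGG16": 138_357_544,
}

# Width of the penultimate feature vector feeding the classification head.
PENULTIMATE_WIDTH: dict[str, int] = {
    "SqueezeNet": 512,
    "MobileNetv2": 1280,
    "Inceptionv1": 1024,
    "DenseNet121": 1024,
    "EfficientNet-B3": 1536,
    "ResNeXt50": 2048,
    "ResNet50": 2048,
    "Inceptionv3": 2048,
    "EfficientNet-B7": 2560,
    "WideResNet50": 2048,
    "VGG16": 4096,
}

Layer = tuple[str, int]


def _conv(cin: int, cout: int, k, groups: int = 1, bias: bool = False) -> int:
    kh, kw = (k, k) if isinstance(k, int) else k
    n = (cin // groups) * cout * kh * kw
    return n + (cout if bias else 0)


def _bn(c: int) -> int:
    return 2 * c


def _fc(din: int, dout: int) -> int:
    return din * dout + dout


# --------------------------------------------------------------------------
# VGG-16
# --------------------------------------------------------------------------

def _vgg16() -> list[Layer]:
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]
    layers: list[Layer] = []
    cin = 3
    i = 0
    for v in cfg:
        if v == "M":
            continue
        layers.append((f"features.conv{i}", _conv(cin, v, 3, bias=True)))
        cin = v
        i += 1
    layers.append(("classifier.fc1", _fc(512 * 7 * 7, 4096)))
    layers.append(("classifier.fc2", _fc(4096, 4096)))
    return layers


# --------------------------------------------------------------------------
# ResNet family (bottleneck): ResNet50, ResNeXt50-32x4d, WideResNet50-2
# --------------------------------------------------------------------------

def _resnet_bottleneck(blocks: list[int], groups: int, base_width: int) -> list[Layer]:
    layers: list[Layer] = [("conv1", _conv(3, 64, 7)), ("bn1", _bn(64))]
    cin = 64
    for stage, (planes, n) in enumerate(zip((64, 128, 256, 512), blocks)):
        width = int(planes * (base_width / 64.0)) * groups
        cout = planes * 4
        for b in range(n):
            p = f"layer{stage + 1}.{b}"
            layers += [
                (f"{p}.conv1", _conv(cin, width, 1)), (f"{p}.bn1", _bn(width)),
                (f"{p}.conv2", _conv(width, width, 3, groups=groups)),
                (f"{p}.bn2", _bn(width)),
                (f"{p}.conv3", _conv(width, cout, 1)), (f"{p}.bn3", _bn(cout)),
            ]
            if b == 0:
                layers += [(f"{p}.downsample.0", _conv(cin, cout, 1)),
                           (f"{p}.downsample.1", _bn(cout))]
            cin = cout
    return layers


def _resnet50() -> list[Layer]:
    return _resnet_bottleneck([3, 4, 6, 3], groups=1, base_width=64)


def _resnext50() -> list[Layer]:
    return _resnet_bottleneck([3, 4, 6, 3], groups=32, base_width=4)


def _wide_resnet50() -> list[Layer]:
    return _resnet_bottleneck([3, 4, 6, 3], groups=1, base_width=128)


# --------------------------------------------------------------------------
# DenseNet-121
# --------------------------------------------------------------------------

def _densenet121() -> list[Layer]:
    growth, bn_size = 32, 4
    layers: list[Layer] = [("conv0", _conv(3, 64, 7)), ("norm0", _bn(64))]
    c = 64
    for bi, n in enumerate((6, 12, 24, 16)):
        for li in range(n):
            p = f"denseblock{bi + 1}.denselayer{li + 1}"
            layers += [
                (f"{p}.norm1", _bn(c)),
                (f"{p}.conv1", _conv(c, bn_size * growth, 1)),
                (f"{p}.norm2", _bn(bn_size * growth)),
                (f"{p}.conv2", _conv(bn_size * growth, growth, 3)),
            ]
            c += growth
        if bi < 3:
            layers += [(f"transition{bi + 1}.norm", _bn(c)),
                       (f"transition{bi + 1}.conv", _conv(c, c // 2, 1))]
            c //= 2
    layers.append(("norm5", _bn(c)))
    return layers


# --------------------------------------------------------------------------
# SqueezeNet v1.1 (head is a 1x1 conv, parameter-equivalent to a dense layer)
# --------------------------------------------------------------------------

def _squeezenet11() -> list[Layer]:
    layers: list[Layer] = [("features.0", _conv(3, 64, 3, bias=True))]
    fires = [(64, 16, 64), (128, 16, 64), (128, 32, 128), (256, 32, 128),
             (256, 48, 192), (384, 48, 192), (384, 64, 256), (512, 64, 256)]
    for i, (cin, s, e) in enumerate(fires):
        p = f"fire{i + 2}"
        layers += [
            (f"{p}.squeeze", _conv(cin, s, 1, bias=True)),
            (f"{p}.expand1x1", _conv(s, e, 1, bias=True)),
            (f"{p}.expand3x3", _conv(s, e, 3, bias=True)),
        ]
    return layers


# --------------------------------------------------------------------------
# MobileNet v2
# --------------------------------------------------------------------------

def _mobilenetv2() -> list[Layer]:
    layers: list[Layer] = [("features.0.conv", _conv(3, 32, 3)),
                           ("features.0.bn", _bn(32))]
    cfg = [(1, 16, 1), (6, 24, 2), (6, 32, 3), (6, 64, 4),
           (6, 96, 3), (6, 160, 3), (6, 320, 1)]
    cin = 32
    idx = 1
    for t, c, n in cfg:
        for _ in range(n):
            hid = cin * t
            p = f"features.{idx}"
            if t != 1:
                layers += [(f"{p}.expand", _conv(cin, hid, 1)),
                           (f"{p}.expand_bn", _bn(hid))]
            layers += [
                (f"{p}.dw", _conv(hid, hid, 3, groups=hid)),
                (f"{p}.dw_bn", _bn(hid)),
                (f"{p}.project", _conv(hid, c, 1)),
                (f"{p}.project_bn", _bn(c)),
            ]
            cin = c
            idx += 1
    layers += [("features.last.conv", _conv(320, 1280, 1)),
               ("features.last.bn", _bn(1280))]
    return layers


# --------------------------------------------------------------------------
# GoogLeNet / Inception v1 (batch-norm variant, no auxiliary heads; the
# "5x5" branch uses 3x3 kernels as in the reference implementation)
# --------------------------------------------------------------------------

def _basic_conv(name: str, cin: int, cout: int, k) -> list[Layer]:
    return [(f"{name}.conv", _conv(cin, cout, k)), (f"{name}.bn", _bn(cout))]


def _googlenet() -> list[Layer]:
    layers = (_basic_conv("conv1", 3, 64, 7)
              + _basic_conv("conv2", 64, 64, 1)
              + _basic_conv("conv3", 64, 192, 3))
    cfg = {
        "3a": (192, 64, 96, 128, 16, 32, 32),
        "3b": (256, 128, 128, 192, 32, 96, 64),
        "4a": (480, 192, 96, 208, 16, 48, 64),
        "4b": (512, 160, 112, 224, 24, 64, 64),
        "4c": (512, 128, 128, 256, 24, 64, 64),
        "4d": (512, 112, 144, 288, 32, 64, 64),
        "4e": (528, 256, 160, 320, 32, 128, 128),
        "5a": (832, 256, 160, 320, 32, 128, 128),
        "5b": (832, 384, 192, 384, 48, 128, 128),
    }
    for tag, (cin, c1, r3, c3, r5, c5, pp) in cfg.items():
        p = f"inception{tag}"
        layers += _basic_conv(f"{p}.branch1", cin, c1, 1)
        layers += _basic_conv(f"{p}.branch2.0", cin, r3, 1)
        layers += _basic_conv(f"{p}.branch2.1", r3, c3, 3)
        layers += _basic_conv(f"{p}.branch3.0", cin, r5, 1)
        layers += _basic_conv(f"{p}.branch3.1", r5, c5, 3)
        layers += _basic_conv(f"{p}.branch4", cin, pp, 1)
    return layers


# --------------------------------------------------------------------------
# Inception v3 (auxiliary branch kept, including its 1000-way classifier;
# only the main head is swapped)
# --------------------------------------------------------------------------

def _inception_a(p: str, cin: int, pool: int) -> list[Layer]:
    return (_basic_conv(f"{p}.branch1x1", cin, 64, 1)
            + _basic_conv(f"{p}.branch5x5_1", cin, 48, 1)
            + _basic_conv(f"{p}.branch5x5_2", 48, 64, 5)
            + _basic_conv(f"{p}.branch3x3dbl_1", cin, 64, 1)
            + _basic_conv(f"{p}.branch3x3dbl_2", 64, 96, 3)
            + _basic_conv(f"{p}.branch3x3dbl_3", 96, 96, 3)
            + _basic_conv(f"{p}.branch_pool", cin, pool, 1))


def _inception_b(p: str, cin: int) -> list[Layer]:
    return (_basic_conv(f"{p}.branch3x3", cin, 384, 3)
            + _basic_conv(f"{p}.branch3x3dbl_1", cin, 64, 1)
            + _basic_conv(f"{p}.branch3x3dbl_2", 64, 96, 3)
            + _basic_conv(f"{p}.branch3x3dbl_3", 96, 96, 3))


def _inception_c(p: str, cin: int, c7: int) -> list[Layer]:
    return (_basic_conv(f"{p}.branch1x1", cin, 192, 1)
            + _basic_conv(f"{p}.branch7x7_1", cin, c7, 1)
            + _basic_conv(f"{p}.branch7x7_2", c7, c7, (1, 7))
            + _basic_conv(f"{p}.branch7x7_3", c7, 192, (7, 1))
            + _basic_conv(f"{p}.branch7x7dbl_1", cin, c7, 1)
            + _basic_conv(f"{p}.branch7x7dbl_2", c7, c7, (7, 1))
            + _basic_conv(f"{p}.branch7x7dbl_3", c7, c7, (1, 7))
            + _basic_conv(f"{p}.branch7x7dbl_4", c7, c7, (7, 1))
            + _basic_conv(f"{p}.branch7x7dbl_5", c7, 192, (1, 7))
            + _basic_conv(f"{p}.branch_pool", cin, 192, 1))


def _inception_d(p: str, cin: int) -> list[Layer]:
    return (_basic_conv(f"{p}.branch3x3_1", cin, 192, 1)
            + _basic_conv(f"{p}.branch3x3_2", 192, 320, 3)
            + _basic_conv(f"{p}.branch7x7x3_1", cin, 192, 1)
            + _basic_conv(f"{p}.branch7x7x3_2", 192, 192, (1, 7))
            + _basic_conv(f"{p}.branch7x7x3_3", 192, 192, (7, 1))
            + _basic_conv(f"{p}.branch7x7x3_4", 192, 192, 3))


def _inception_e(p: str, cin: int) -> list[Layer]:
    return (_basic_conv(f"{p}.branch1x1", cin, 320, 1)
            + _basic_conv(f"{p}.branch3x3_1", cin, 384, 1)
            + _basic_conv(f"{p}.branch3x3_2a", 384, 384, (1, 3))
            + _basic_conv(f"{p}.branch3x3_2b", 384, 384, (3, 1))
            + _basic_conv(f"{p}.branch3x3dbl_1", cin, 448, 1)
            + _basic_conv(f"{p}.branch3x3dbl_2", 448, 384, 3)
            + _basic_conv(f"{p}.branch3x3dbl_3a", 384, 384, (1, 3))
            + _basic_conv(f"{p}.branch3x3dbl_3b", 384, 384, (3, 1))
            + _basic_conv(f"{p}.branch_pool", cin, 192, 1))


def _inceptionv3() -> list[Layer]:
    layers = (_basic_conv("Conv2d_1a_3x3", 3, 32, 3)
              + _basic_conv("Conv2d_2a_3x3", 32, 32, 3)
              + _basic_conv("Conv2d_2b_3x3", 32, 64, 3)
              + _basic_conv("Conv2d_3b_1x1", 64, 80, 1)
              + _basic_conv("Conv2d_4a_3x3", 80, 192, 3))
    layers += _inception_a("Mixed_5b", 192, 32)
    layers += _inception_a("Mixed_5c", 256, 64)
    layers += _inception_a("Mixed_5d", 288, 64)
    layers += _inception_b("Mixed_6a", 288)
    layers += _inception_c("Mixed_6b", 768, 128)
    layers += _inception_c("Mixed_6c", 768, 160)
    layers += _inception_c("Mixed_6d", 768, 160)
    layers += _inception_c("Mixed_6e", 768, 192)
    # auxiliary classifier branch (kept at 1000 classes)
    layers += _basic_conv("AuxLogits.conv0", 768, 128, 1)
    layers += _basic_conv("AuxLogits.conv1", 128, 768, 5)
    layers += [("AuxLogits.fc", _fc(768, 1000))]
    layers += _inception_d("Mixed_7a", 768)
    layers += _inception_e("Mixed_7b", 1280)
    layers += _inception_e("Mixed_7c", 2048)
    return layers


# --------------------------------------------------------------------------
# EfficientNet B3 / B7
# --------------------------------------------------------------------------

def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _efficientnet(width_mult: float, depth_mult: float) -> list[Layer]:
    # (expand_ratio, kernel, base_channels_out, base_num_layers)
    base = [(1, 3, 16, 1), (6, 3, 24, 2), (6, 5, 40, 2), (6, 3, 80, 3),
            (6, 5, 112, 3), (6, 5, 192, 4), (6, 3, 320, 1)]
    stem = _make_divisible(32 * width_mult)
    layers: list[Layer] = [("features.0.conv", _conv(3, stem, 3)),
                           ("features.0.bn", _bn(stem))]
    cin = stem
    for si, (t, k, c, n) in enumerate(base):
        cout = _make_divisible(c * width_mult)
        reps = int(math.ceil(n * depth_mult))
        for b in range(reps):
            p = f"features.{si + 1}.{b}"
            hid = cin * t
            if t != 1:
                layers += [(f"{p}.expand", _conv(cin, hid, 1)),
                           (f"{p}.expand_bn", _bn(hid))]
            layers += [(f"{p}.dw", _conv(hid, hid, k, groups=hid)),
                       (f"{p}.dw_bn", _bn(hid))]
            sq = max(1, cin // 4)  # squeeze-excite sized from block input
            layers += [(f"{p}.se.fc1", _conv(hid, sq, 1, bias=True)),
                       (f"{p}.se.fc2", _conv(sq, hid, 1, bias=True))]
            layers += [(f"{p}.project", _conv(hid, cout, 1)),
                       (f"{p}.project_bn", _bn(cout))]
            cin = cout
    head = 4 * cin
    layers += [("features.top.conv", _conv(cin, head, 1)),
               ("features.top.bn", _bn(head))]
    return layers


_BUILDERS: dict[str, Callable[[], list[Layer]]] = {
    "SqueezeNet": _squeezenet11,
    "MobileNetv2": _mobilenetv2,
    "Inceptionv1": _googlenet,
    "DenseNet121": _densenet121,
    "EfficientNet-B3": lambda: _efficientnet(1.2, 1.4),
    "ResNeXt50": _resnext50,
    "ResNet50": _resnet50,
    "Inceptionv3": _inceptionv3,
    "EfficientNet-B7": lambda: _efficientnet(2.0, 3.1),
    "WideResNet50": _wide_resnet50,
    "VGG16": _vgg16,
}

ARCH_NAMES: tuple[str, ...] = tuple(_BUILDERS)


def backbone_layers(arch_name: str) -> list[Layer]:
    """Named trainable layers of the backbone, classifier head excluded."""
    try:
        return _BUILDERS[arch_name]()
    except KeyError:
        raise ValueError(f"unknown architecture: {arch_name!r}") from None


def head_swap_count(arch_name: str, n_classes: int) -> int:
    """Expected total parameters from the published 1000-class count.

    Swapping only the final dense layer gives
    ``published - (d*1000 + 1000) + (d*n + n)`` with d the penultimate width.
    """
    d = PENULTIMATE_WIDTH[arch_name]
    return (IMAGENET_PARAM_COUNTS[arch_name]
            - _fc(d, 1000) + _fc(d, n_classes))
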