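>nbarc_synth_01 synthetic NB-ARC-like seed row
IVGIYGMGGVGKATLAYAVYFNLERVKEHFDLRAWVCVSQDFDVKKYALLLDDVWPEDQGLPLA
>nbarc_synth_02 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTTLARAVY-NDDRVKEHFHLRAAVCVSQDFDVKK-LHVLQDVWNEAQGLPLA
>nbarc_synth_03 synthetic NB-ARC-like seed row
IVGIYGMGKV-KTTLARAVY-NDERVKEHFDLRAWVCVVADFDVKK-LLVLDDSWNYDQGLPLA
>nbarc_synth_04 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTTLARAVYVNDERVKEAFDLRAWVIVMQDFDVKKSLLVLDDVWNEDQGLPLA
>nbarc_synth_05 synthetic NB-ARC-like seed row
DVGIYGMGGVGKTTLARAVY-DDEAVKEHFDLRAWVCVSQDFDVKK-LLVLDDVWNEDQGLPLC
>nbarc_synth_06 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTQLARAVY-NDERVKEYFDLRAWVCVSFDFDVKK-LLVLDDVWNEDFGLPLA
>nbarc_synth_07 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTTLARIVYINDERVKEHFDLRAWVCVSQDFDVKKCLLVLDDVWNQDQGLPDA
>nbarc_synth_08 synthetic NB-ARC-like seed row
IVGIYGDGGV-KTTLARAVY-NDERVQEHFVLRAWVCVSQDFDVKK-LLVLDDVWNEDQGLPLA
>nbarc_synth_09 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTTLARAVY-NDERVKEHFDLWAWVDVSQDFDVKK-LILIDDVQNEDQGLPLA
>nbarc_synth_10 synthetic NB-ARC-like seed row
IVGIYGFGGVGKTTLARAVYSNDERKKEHFDLRAVVCVSADFDVKKTLLVLDDVWNECQLLPLA
>nbarc_synth_11 synthetic NB-ARC-like seed row
IVGIYGMGGVGKTTLARAVY-NDEKVKEHFDLRAWVCVSQDFDVKK-LCPQDDVWNEDQGLPLA
>nbarc_synth_12 synthetic NB-ARC-like seed row
IVGIYGDGGVGKTTLARAVQ-NDERVKEHFDLRAWVCVSQDFDVKK-LLVLGDVENEDDGLPRA
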