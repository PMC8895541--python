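# Synthetic empirical-style amino-acid exchangeability matrix (PAML format).
# Generated deterministically; NOT a published matrix. Order: ARNDCQEGHILKMFPSTWYV.
0.0748
0.8724 2.5920
4.3166 1.7439 0.2325
0.6141 0.9815 0.8316 0.9105
0.3811 0.4666 0.1429 3.3013 0.7165
1.9516 1.4454 0.8441 0.5689 1.2420 0.6504
0.6774 1.0377 2.2692 1.7638 0.8516 1.5282 0.8345
0.1600 0.6611 0.1171 4.4464 3.2324 4.4560 0.3514 1.3413
2.1024 0.1649 0.7819 1.4161 0.6869 0.6420 0.8687 0.3668 0.2575
1.1935 1.0366 0.2688 0.4294 0.6725 0.1940 4.1151 1.8376 2.4022 0.3639
3.0626 0.5830 0.2284 2.7222 0.2326 0.6515 1.4702 1.6186 6.0628 2.9350 0.1623
0.3922 0.4966 1.1391 0.6223 0.9013 0.1188 3.2300 0.5884 0.3080 0.6430 1.1237 0.7535
0.2179 3.1313 0.6545 0.4844 0.9403 1.0214 1.5056 5.7305 0.1286 0.8390 0.4893 0.8634 1.5488
1.7437 0.3583 0.3137 1.6125 1.4956 0.6861 2.0402 0.4318 0.3753 0.6214 0.2776 0.2622 1.1648 7.3308
1.4475 5.1254 1.1136 1.0578 0.2302 3.6688 2.0028 4.9978 4.8464 1.3857 2.3061 0.4064 1.3912 0.4198 0.5528
2.0843 0.8180 2.8250 0.1925 0.4308 0.9070 6.8718 2.4267 1.4656 0.5580 0.3806 1.6869 1.1517 1.4906 0.1945 0.5197
3.4636 0.5903 0.9555 2.2966 1.8449 3.3430 0.4301 3.5654 0.3136 4.0886 0.6977 1.6108 2.0142 0.9835 1.1254 0.5192 0.3225
0.2357 0.0549 3.0962 0.8522 0.4126 1.0279 6.0498 0.2481 5.4942 1.7379 4.9453 5.2099 0.4579 0.1061 1.4370 1.0134 1.9796 0.3111
0.2889 0.7746 1.5701 1.1021 0.4106 0.2178 1.3069 1.3685 0.9824 1.3275 0.9045 0.6348 0.2045 0.7403 0.4954 2.0539 0.6712 0.4668 1.2407

0.053517 0.028856 0.036857 0.085183 0.058201 0.069724 0.038504 0.070063 0.073963 0.050455 0.035239 0.077228 0.027316 0.038256 0.035686 0.038254 0.035389 0.058124 0.039529 0.049656
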