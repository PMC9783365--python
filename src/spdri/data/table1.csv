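led_id,side,position_px,intensity_uW,exposure_ms_10um,exposure_ms_20um
1,long_axis,1722,12.0,115,200
2,long_axis,1875,5.1,270,480
3,long_axis,2055,0.7,1900,3450
4,short_axis,2336,12.4,180,270
5,short_axis,1947,1.6,1300,1900
6,short_axis,1736,5.7,380,540
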