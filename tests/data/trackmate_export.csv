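LABEL,ID,TRACK_ID,QUALITY,POSITION_X,POSITION_Y,POSITION_Z,POSITION_T,FRAME,RADIUS,VISIBILITY,MEAN_INTENSITY_CH1
Label,Spot ID,Track ID,Quality,X,Y,Z,T,Frame,Radius,Visibility,Mean intensity ch1
,,,(quality),(pixel),(pixel),(pixel),(sec),,,(pixel),
ID1,1,0,12.5,10.0,20.0,0,0,0,5,1,180.2
ID2,2,0,11.9,12.5,21.0,0,120,1,5,1,176.4
ID3,3,0,13.1,14.0,22.5,0,240,2,5,1,181.0
ID4,4,3,9.8,100.0,50.0,0,0,0,5,1,150.7
ID5,5,3,10.2,98.5,52.0,0,120,1,5,1,149.9
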