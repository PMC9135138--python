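x,y,z,w,noise1,noise2
n,o,n,n,v,w
o,o,o,n,w,v
a,o,c,d,w,v
n,n,n,n,w,v
a,b,c,d,u,u
a,o,c,d,v,u
o,o,o,n,w,u
n,n,o,n,v,v
a,n,o,n,v,v
n,b,n,n,v,v
a,b,c,n,v,v
a,o,c,d,u,v
a,o,c,d,w,v
a,b,n,d,w,w
a,n,n,n,v,u
n,o,c,n,u,v
o,b,n,n,u,w
a,b,n,d,v,v
a,b,c,d,u,u
a,b,c,d,u,u
o,o,o,n,v,w
a,b,c,d,w,w
a,o,c,d,w,v
a,n,n,n,u,u
a,b,n,d,v,v
a,b,n,d,v,u
n,n,n,n,w,v
o,n,o,n,v,u
a,b,n,d,w,v
n,o,n,n,w,w
a,o,c,d,v,w
n,o,c,n,w,u
o,b,o,d,v,w
a,b,n,d,v,u
n,o,c,n,v,w
n,n,o,n,w,u
a,o,n,n,v,u
a,o,c,d,v,u
a,o,o,n,v,v
a,o,n,n,w,w
o,o,n,d,w,u
a,o,o,n,v,u
a,o,n,n,v,u
a,n,n,n,w,w
a,o,o,n,u,u
o,b,o,n,v,v
a,b,n,d,v,u
o,o,n,n,u,u
o,b,o,n,u,u
n,n,o,n,u,u
a,b,n,d,v,u
o,b,o,n,w,w
n,o,c,n,u,w
a,n,o,n,v,v
a,b,n,d,w,v
o,b,n,n,w,w
o,o,o,n,u,w
n,n,n,n,v,v
o,b,o,n,v,v
a,b,n,d,v,v
a,b,n,d,w,u
a,n,n,n,v,v
n,b,o,n,u,v
a,o,c,d,w,u
a,b,n,d,v,u
o,o,o,n,u,u
a,o,c,d,v,v
n,o,c,n,u,u
o,o,c,n,v,v
a,o,c,d,w,u
a,b,c,n,w,u
o,o,o,d,v,u
a,n,n,n,v,u
o,o,n,n,u,u
n,o,n,n,w,u
o,o,o,n,v,u
a,o,c,d,v,v
a,o,c,d,u,w
a,b,n,d,v,v
a,b,n,d,u,v
a,n,n,n,w,v
a,o,c,d,w,v
a,o,n,n,v,u
a,b,c,d,w,v
a,o,c,d,u,w
a,n,n,n,u,v
a,b,n,d,w,w
a,o,o,n,u,v
n,b,n,n,v,u
a,b,c,n,u,w
a,b,c,d,v,w
n,o,c,n,v,v
a,o,c,d,u,u
o,b,n,n,w,w
a,n,o,n,w,v
o,n,c,n,w,u
n,b,o,n,w,v
a,b,c,n,w,w
n,n,c,n,w,w
o,b,o,n,u,v
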